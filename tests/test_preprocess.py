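import numpy as np
import pandas as pd
import pytest

from flimpipe.preprocess import (
    QualityThresholds,
    apply_quality_filters,
    calibrate_gain_thresholds,
    estimate_snr_db,
    subtract_background,
    upsample,
)
from flimpipe.records import WaveformSet


def make_ws(samples, gains=None, rate=2.5e9):
    samples = np.asarray(samples, dtype=float)
    n = samples.shape[0]
    if gains is None:
        gains = np.full((n, 3), 100.0)
    return WaveformSet(
        samples=samples,
        gains=np.asarray(gains, dtype=float),
        xy_mm=np.zeros((n, 2)),
        point_ids=np.arange(n),
        patient_id="P01",
        phase="in_vivo",
        sample_rate=rate,
    )


# -- background subtraction -------------------------------------------------


def test_subtract_zero_background_is_identity():
    ws = make_ws(np.random.default_rng(0).normal(size=(2, 3, 64)))
    out = subtract_background(ws, np.zeros((3, 64)))
    np.testing.assert_array_equal(out.samples, ws.samples)


def test_subtract_signal_itself_annihilates():
    sig = np.random.default_rng(1).normal(size=(3, 64))
    ws = make_ws(sig[None])
    out = subtract_background(ws, sig)
    np.testing.assert_array_equal(out.samples, np.zeros((1, 3, 64)))


def test_subtract_known_fiber_template_leaves_signal():
    rng = np.random.default_rng(2)
    t = np.arange(128) * 0.4
    signal = np.exp(-t / 4.0)[None, None, :] * np.ones((1, 3, 1))
    template = 0.3 * np.exp(-t / 1.5)[None, :] * np.ones((3, 1))
    ws = make_ws(signal + template[None])
    out = subtract_background(ws, template)
    np.testing.assert_allclose(out.samples, signal, atol=1e-12)


def test_subtract_length_mismatch_raises():
    ws = make_ws(np.zeros((1, 3, 64)))
    with pytest.raises(ValueError):
        subtract_background(ws, np.zeros((3, 32)))


# -- upsampling -------------------------------------------------------------


def test_upsample_count_2p5_to_12p5_gs():
    """1000 samples at 2.5 GS/s become 5000 samples at 12.5 GS/s."""
    ws = make_ws(np.random.default_rng(3).normal(size=(1, 3, 1000)))
    out = upsample(ws, 12.5e9)
    assert out.samples.shape == (1, 3, 5000)
    assert out.sample_rate == 12.5e9


def test_upsample_preserves_constant_series():
    ws = make_ws(np.full((1, 3, 200), 2.5))
    out = upsample(ws, 12.5e9)
    np.testing.assert_allclose(out.samples, 2.5, rtol=1e-3)
    # interior ripple is at the filter's passband level; edges carry the
    # (trimmed-tolerance) transient
    np.testing.assert_allclose(out.samples[:, :, 60:-60], 2.5, rtol=1e-5)


def test_upsample_matches_analytic_sinusoid():
    """A sinusoid well below the original Nyquist is reproduced on the fine
    grid within 1e-3 of its amplitude."""
    rate, factor = 2.5e9, 5
    n = 400
    t = np.arange(n) / rate
    f = 0.2 * (rate / 2)  # 20% of Nyquist
    ws = make_ws(np.sin(2 * np.pi * f * t)[None, None, :] * np.ones((1, 3, 1)))
    out = upsample(ws, rate * factor)
    t_up = np.arange(n * factor) / (rate * factor)
    expected = np.sin(2 * np.pi * f * t_up)
    # exclude one interpolation-filter length at each end (edge transient)
    err = np.abs(out.samples[0, 0] - expected)[50:-50]
    assert err.max() < 1e-3


def test_upsample_non_integer_ratio_rejected():
    ws = make_ws(np.zeros((1, 3, 64)))
    with pytest.raises(ValueError):
        upsample(ws, 6.0e9)


def test_background_and_upsampling_commute_with_gain_scale():
    """Scaling a record by a constant commutes with subtract+upsample."""
    rng = np.random.default_rng(4)
    sig = rng.normal(size=(2, 3, 100))
    bg = rng.normal(size=(3, 100))
    scale = 3.7
    ws = make_ws(sig)
    ws_scaled = make_ws(sig * scale)
    a = upsample(subtract_background(ws_scaled, bg * scale), 12.5e9)
    b = upsample(subtract_background(ws, bg), 12.5e9)
    np.testing.assert_allclose(a.samples, b.samples * scale, rtol=1e-9, atol=1e-9)


# -- SNR and quality filtering ---------------------------------------------


def test_snr_estimate_matches_known_noise():
    rng = np.random.default_rng(5)
    n = 1200
    noise_sd = 0.01
    sig = np.zeros((1, 3, n))
    sig[:, :, 400] = 1.0  # peak well after the baseline segment
    sig += rng.normal(0, noise_sd, sig.shape)
    snr = estimate_snr_db(make_ws(sig))
    assert snr.shape == (1, 3)
    np.testing.assert_allclose(snr, 20 * np.log10(1.0 / noise_sd), atol=2.0)


def clean_samples(n, peak=1.0):
    t = np.arange(64) * 0.4
    base = peak * np.exp(-t / 4.0)
    out = np.tile(base, (n, 3, 1))
    out[:, :, :8] = 0.0
    return out


def test_gain_filter_rejects_channel1_high_gain():
    ws = make_ws(clean_samples(1), gains=[[400.0, 500.0, 700.0]])
    kept, rejected = apply_quality_filters(ws, QualityThresholds(), snr_db=np.full((1, 3), 40.0))
    assert kept.n_points == 0 and rejected.n_points == 1
    assert "gain_ch1_high" in rejected.flags[0]


def test_gain_filter_keeps_in_range_point():
    ws = make_ws(clean_samples(1), gains=[[100.0, 500.0, 700.0]])
    kept, rejected = apply_quality_filters(ws, QualityThresholds(), snr_db=np.full((1, 3), 40.0))
    assert kept.n_points == 1 and rejected.n_points == 0


def test_low_gain_bound_applies_to_channel1_only():
    ws = make_ws(clean_samples(2), gains=[[10.0, 500.0, 700.0], [100.0, 5.0, 5.0]])
    kept, rejected = apply_quality_filters(ws, QualityThresholds(), snr_db=np.full((2, 3), 40.0))
    assert "gain_ch1_low" in rejected.flags[0]
    assert kept.n_points == 1  # low gain on ch2/ch3 is not a rejection


def test_filtering_conserves_points_and_is_idempotent():
    rng = np.random.default_rng(6)
    gains = np.column_stack(
        [rng.uniform(5, 400, 30), rng.uniform(100, 900, 30), rng.uniform(100, 900, 30)]
    )
    ws = make_ws(clean_samples(30, peak=1.0), gains=gains)
    snr = rng.uniform(10, 40, (30, 3))
    kept, rejected = apply_quality_filters(ws, QualityThresholds(), snr_db=snr)
    assert kept.n_points + rejected.n_points == 30
    kept_idx = np.isin(ws.point_ids, kept.point_ids)
    kept2, rejected2 = apply_quality_filters(kept, QualityThresholds(), snr_db=snr[kept_idx])
    assert kept2.n_points == kept.n_points and rejected2.n_points == 0


def test_empty_input_filters_to_empty():
    ws = make_ws(np.zeros((0, 3, 64)), gains=np.zeros((0, 3)) + 1)
    kept, rejected = apply_quality_filters(ws, QualityThresholds(), snr_db=np.zeros((0, 3)))
    assert kept.n_points == 0 and rejected.n_points == 0


# -- gain-threshold calibration ----------------------------------------------


def profile_data(sd_by_bin: dict, n_per_bin: int = 40, seed: int = 0):
    """Construct (gains, lifetimes) whose per-bin lifetime SD is as given."""
    rng = np.random.default_rng(seed)
    gains, taus = [], []
    for g, sd in sd_by_bin.items():
        gains.append(np.full(n_per_bin, g - 10.0))  # falls into bin value g
        taus.append(4.0 + rng.normal(0, sd, n_per_bin))
    g = np.concatenate(gains)
    t = np.concatenate(taus)
    return np.column_stack([g] * 3), np.column_stack([t] * 3)


def test_calibration_finds_sd_change_point():
    """Flat lifetime SD up to gain 300 then tripled -> threshold 300."""
    sd = {g: 0.1 for g in range(50, 1001, 50)}
    for g in range(350, 1001, 50):
        sd[g] = 0.31
    gains, taus = profile_data(sd)
    thresholds, profile = calibrate_gain_thresholds(gains, taus)
    assert thresholds.gain_high == (300.0, 300.0, 300.0)
    assert set(profile["gain_bin"]) == set(np.arange(50.0, 1001.0, 50.0))


def test_calibration_flat_profile_keeps_range_max():
    gains, taus = profile_data({g: 0.1 for g in range(50, 1001, 50)})
    thresholds, _ = calibrate_gain_thresholds(gains, taus)
    assert thresholds.gain_high == (1000.0, 1000.0, 1000.0)


def test_calibration_evaluates_twenty_bins():
    """Steps of 50 from 50 to 1000 give exactly 20 gain bins per channel."""
    gains, taus = profile_data({g: 0.1 for g in range(50, 1001, 50)})
    _, profile = calibrate_gain_thresholds(gains, taus)
    assert (profile.groupby("channel").size() == 20).all()


def test_calibration_needs_two_populated_bins():
    gains, taus = profile_data({100: 0.1})
    with pytest.raises(ValueError):
        calibrate_gain_thresholds(gains, taus)


def test_quality_thresholds_validation():
    with pytest.raises(ValueError):
        QualityThresholds(gain_low=(500.0, None, None), gain_high=(300.0, 800.0, 800.0))
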