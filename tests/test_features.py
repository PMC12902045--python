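import numpy as np
import pandas as pd
import pytest

from flimpipe.features import (
    PhasorConfig,
    average_lifetime,
    extract_features,
    feature_columns,
    intensity_ratios,
    phasor_coordinates,
)
from flimpipe.instrument import InstrumentModel
from flimpipe.preprocess import subtract_background, upsample
from flimpipe.records import WaveformSet
from flimpipe.synthetic import CohortConfig, _forward_convolve, generate_cohort


# -- average lifetime --------------------------------------------------------


def test_lifetime_of_delta_at_origin_is_zero():
    h = np.zeros(1000)
    h[0] = 5.0
    assert average_lifetime(h, 0.08) == 0.0


def test_lifetime_of_truncated_exponential_matches_closed_form():
    """exp(-t/4) over an 80 ns window: tau (1 - (T/tau) e^{-T/tau} /
    (1 - e^{-T/tau})) evaluated numerically, ~3.99 ns at the grid level."""
    dt, n, tau, T = 0.08, 1000, 4.0, 80.0
    t = np.arange(n) * dt
    h = np.exp(-t / tau)
    expected = tau * (1 - (T / tau) * np.exp(-T / tau) / (1 - np.exp(-T / tau)))
    assert average_lifetime(h, dt) == pytest.approx(expected, abs=0.05)
    # exact closed form of the discrete estimator itself (geometric sums):
    # sum n r^n / sum r^n over n < N, r = exp(-dt/tau)
    r = np.exp(-dt / tau)
    N = n
    num = r * (1 - N * r ** (N - 1) + (N - 1) * r**N) / (1 - r) ** 2
    den = (1 - r**N) / (1 - r)
    assert average_lifetime(h, dt) == pytest.approx(dt * num / den, abs=1e-9)


def test_lifetime_scale_invariance():
    rng = np.random.default_rng(0)
    h = np.abs(rng.normal(size=500))
    assert average_lifetime(3.7 * h, 0.08) == pytest.approx(average_lifetime(h, 0.08))


def test_lifetime_invariant_to_upsampling_factor():
    t1 = np.arange(250) * 0.32
    t2 = np.arange(1000) * 0.08
    tau1 = average_lifetime(np.exp(-t1 / 4.0), 0.32)
    tau2 = average_lifetime(np.exp(-t2 / 4.0), 0.08)
    assert tau1 == pytest.approx(tau2, abs=0.15)


def test_lifetime_of_nonpositive_decay_is_nan():
    assert np.isnan(average_lifetime(np.zeros(100), 0.08))
    assert np.isnan(average_lifetime(-np.ones(100), 0.08))


# -- phasors -----------------------------------------------------------------


def test_phasor_of_delta_is_unit():
    h = np.zeros(1000)
    h[0] = 1.0
    ph = phasor_coordinates(h, 0.08)
    np.testing.assert_allclose(ph, [[1.0, 0.0], [1.0, 0.0]], atol=1e-12)


def test_phasor_of_mono_exponential_matches_closed_form():
    """tau=4 ns, 12.5 MHz fundamental, harmonic 1: g = 1/(1+(wt)^2),
    s = wt/(1+(wt)^2) with wt = 2 pi * 12.5 MHz * 4 ns = 0.31416."""
    dt, n = 0.08, 1000
    h = np.exp(-np.arange(n) * dt / 4.0)
    g, s = phasor_coordinates(h, dt)[0]
    wt = 2 * np.pi * 12.5e6 * 4e-9
    assert g == pytest.approx(1 / (1 + wt**2), abs=0.005)
    assert s == pytest.approx(wt / (1 + wt**2), abs=0.005)
    assert (g, s) == pytest.approx((0.9102, 0.2859), abs=0.005)


@pytest.mark.parametrize("tau", [1.0, 2.5, 4.0, 8.0])
def test_mono_exponentials_lie_on_universal_semicircle(tau):
    # fine grid keeps the discrete-sum quadrature error below the tolerance
    dt, n = 0.02, 4000
    h = np.exp(-np.arange(n) * dt / tau)
    for g, s in phasor_coordinates(h, dt):
        assert (g - 0.5) ** 2 + s**2 == pytest.approx(0.25, abs=1e-3)


def test_bi_exponential_mixture_lies_inside_semicircle():
    dt, n = 0.08, 1000
    t = np.arange(n) * dt
    h = 0.5 * np.exp(-t / 1.0) + 0.5 * np.exp(-t / 8.0)
    g, s = phasor_coordinates(h, dt)[0]
    assert (g - 0.5) ** 2 + s**2 < 0.25 - 1e-3


def test_phasor_zero_intensity_flagged_nan():
    assert np.isnan(phasor_coordinates(np.zeros(100), 0.08)).all()


def test_phasor_config_validation():
    with pytest.raises(ValueError):
        PhasorConfig(harmonics=(1, 1))
    with pytest.raises(ValueError):
        PhasorConfig(harmonics=(0,))


# -- intensity ratios --------------------------------------------------------


def test_intensity_ratio_arithmetic():
    r, valid = intensity_ratios(np.array([2.0, 1.0, 1.0]))
    assert valid
    np.testing.assert_allclose(r, [0.5, 0.25, 0.25])


def test_intensity_ratio_degenerate_single_channel():
    r, valid = intensity_ratios(np.array([5.0, 0.0, 0.0]))
    assert valid
    np.testing.assert_allclose(r, [1.0, 0.0, 0.0])


def test_intensity_ratio_zero_sum_invalid():
    r, valid = intensity_ratios(np.array([0.0, 0.0, 0.0]))
    assert not valid
    assert np.isnan(r).all()


def test_intensity_ratios_sum_to_one_batch():
    rng = np.random.default_rng(1)
    inten = rng.uniform(0.1, 5.0, (40, 3))
    r, valid = intensity_ratios(inten)
    assert valid.all()
    np.testing.assert_allclose(r.sum(axis=1), 1.0, atol=1e-9)


# -- full extraction ---------------------------------------------------------


@pytest.fixture(scope="module")
def extracted(instrument):
    cfg = CohortConfig(
        phase="in_vivo", n_patients=1, n_mixed=1, n_healthy_only=0,
        points_per_class=30, target_snr_db=300.0, background_level=0.0, rng_seed=13,
    )
    cohort = generate_cohort(cfg, instrument)
    patient = cohort.patients[0]
    ws = upsample(patient.waveforms, instrument.sample_rate_up)
    return extract_features(ws, instrument), patient.truth


def test_feature_cardinality(extracted):
    """Each point yields 3 lifetimes, 3 IRs, 36 Laguerre coefficients and
    12 phasor values."""
    feats, _ = extracted
    assert len([c for c in feats if c.startswith("lifetime_")]) == 3
    assert len([c for c in feats if c.startswith("ir_")]) == 3
    assert len([c for c in feats if c.startswith("laguerre_")]) == 36
    assert len([c for c in feats if c.startswith("phasor_")]) == 12


def test_noiseless_lifetimes_recovered_within_tenth_ns(extracted):
    feats, truth = extracted
    m = feats.set_index("point_id")
    tr = truth.set_index("point_id").loc[m.index]
    # channel 3's slowest decays lose tail mass to the 80 ns window, so its
    # tolerance reflects the truncated (observable) moment
    tol = {1: 0.1, 2: 0.1, 3: 0.2}
    for k in (1, 2, 3):
        err = m[f"lifetime_ch{k}"] - tr[f"true_lifetime_ch{k}"]
        assert np.abs(err).max() < tol[k], f"channel {k}"


def test_noiseless_intensity_ratios_recovered(extracted):
    feats, truth = extracted
    m = feats.set_index("point_id")
    tr = truth.set_index("point_id").loc[m.index]
    for k in (1, 2, 3):
        err = m[f"ir_ch{k}"] - tr[f"true_ir_ch{k}"]
        assert np.abs(err).max() < 0.01, f"channel {k}"


def test_extraction_is_bit_stable(extracted, instrument):
    feats, _ = extracted
    cfg = CohortConfig(
        phase="in_vivo", n_patients=1, n_mixed=1, n_healthy_only=0,
        points_per_class=30, target_snr_db=300.0, background_level=0.0, rng_seed=13,
    )
    cohort = generate_cohort(cfg, instrument)
    ws = upsample(cohort.patients[0].waveforms, instrument.sample_rate_up)
    again = extract_features(ws, instrument)
    pd.testing.assert_frame_equal(feats, again)


def test_extraction_requires_upsampled_grid(instrument, small_cohort):
    with pytest.raises(ValueError):
        extract_features(small_cohort.patients[0].waveforms, instrument)


def test_invalid_channel_marks_point_incomplete(instrument):
    cfg = CohortConfig(
        phase="in_vivo", n_patients=1, n_mixed=1, n_healthy_only=0,
        points_per_class=4, target_snr_db=300.0, background_level=0.0, rng_seed=17,
    )
    cohort = generate_cohort(cfg, instrument)
    ws = cohort.patients[0].waveforms
    ws.samples[0, 2, :] = 0.0  # kill channel 3 of the first point
    feats = extract_features(upsample(ws, instrument.sample_rate_up), instrument)
    assert bool(feats.loc[0, "incomplete"])
    assert not feats.loc[1:, "incomplete"].any()


def test_feature_group_column_resolution():
    cols = ["lifetime_ch1", "ir_ch2", "laguerre_c01_ch3", "phasor_g1_ch1", "snr_ch1", "label"]
    assert feature_columns(cols, ("lifetimes",)) == ["lifetime_ch1"]
    assert feature_columns(cols, ("laguerre", "phasors")) == ["laguerre_c01_ch3", "phasor_g1_ch1"]
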