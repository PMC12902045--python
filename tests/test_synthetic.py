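import numpy as np
import pandas as pd
import pytest

from flimpipe.instrument import InstrumentModel
from flimpipe.synthetic import (
    CohortConfig,
    DecayParams,
    generate_cohort,
    preset_tissue_models,
    synthesize_waveform,
)


def direct_cohens_d(truth: pd.DataFrame, column: str) -> float:
    """Independent effect-size oracle: within-subject mean difference over
    pooled within-cell SD, computed directly from the ground-truth table."""
    demeaned = truth.copy()
    cell_means = truth.groupby(["patient_id", "label"])[column].transform("mean")
    demeaned["resid"] = truth[column] - cell_means
    sigma = demeaned["resid"].std(ddof=1)
    mixed = truth[truth.groupby("patient_id")["label"].transform("nunique") == 2]
    diffs = mixed.groupby(["patient_id", "label"])[column].mean().unstack()
    return float((diffs["cancer"] - diffs["healthy"]).mean() / sigma)


def test_fixed_seed_cohorts_are_identical(small_cohort, instrument):
    again = generate_cohort(small_cohort.config, instrument)
    pd.testing.assert_frame_equal(small_cohort.truth, again.truth)
    for a, b in zip(small_cohort.patients, again.patients):
        np.testing.assert_array_equal(a.waveforms.samples, b.waveforms.samples)
        np.testing.assert_array_equal(a.mask.label_raster, b.mask.label_raster)


def test_cohort_structure_matches_study_design():
    """13 patients carry both tissue classes; 2 carry only healthy tissue."""
    cfg = CohortConfig(points_per_class=1500, synthesize_waveforms=False, rng_seed=5)
    truth = generate_cohort(cfg).truth
    per_patient = truth.groupby("patient_id")["label"].agg(set)
    assert len(per_patient) == 15
    assert sum(labels == {"cancer", "healthy"} for labels in per_patient) == 13
    assert sum(labels == {"healthy"} for labels in per_patient) == 2
    assert truth.groupby("label").size()["cancer"] == 1500
    assert truth.groupby("label").size()["healthy"] == 1500


@pytest.mark.parametrize(
    "phase,column,target",
    [("in_vivo", "true_lifetime_ch1", -0.74), ("ex_vivo", "true_ir_ch3", 1.0)],
)
def test_calibrated_effect_sizes_recovered_from_truth(truth_cohorts, phase, column, target):
    """The generator's headline class separations hit their calibrated
    Cohen's d within +/-0.05 at 20k points per class."""
    d = direct_cohens_d(truth_cohorts[phase], column)
    assert d == pytest.approx(target, abs=0.05)


def test_invalid_configs_rejected():
    with pytest.raises(ValueError):
        CohortConfig(n_patients=15, n_mixed=10, n_healthy_only=2)
    with pytest.raises(ValueError):
        CohortConfig(points_per_class=0)
    with pytest.raises(ValueError):
        generate_cohort(
            CohortConfig(points_per_class=10, synthesize_waveforms=False),
            tissue_models={"healthy": preset_tissue_models("in_vivo")["healthy"]},
        )
    with pytest.raises(ValueError):
        preset_tissue_models("post_mortem")


def test_mono_exponential_delta_irf_forward_model():
    """With a near-delta IRF and no noise the waveform is exp(-t/4ns)."""
    inst = InstrumentModel(irf_fwhm_ps=1e-3, detector_fwhm_ns=1e-4, pulse_delay_ns=0.0)
    decay = DecayParams(
        amplitudes=np.ones((3, 1)), lifetimes_ns=np.full((3, 1), 4.0), peak=np.ones(3)
    )
    samples, flags = synthesize_waveform(decay, inst, gain=np.full(3, 100.0))
    t = inst.time_axis_ns(upsampled=False)
    expected = np.exp(-t / 4.0)
    ratio = samples[0] / samples[0, 0]
    np.testing.assert_allclose(ratio, expected, rtol=0, atol=5e-3)
    assert "truncation_bias" not in flags


def test_truncation_flag_when_window_too_short():
    inst = InstrumentModel(window_ns=8.0, pulse_delay_ns=1.0)
    decay = DecayParams(
        amplitudes=np.ones((3, 1)), lifetimes_ns=np.full((3, 1), 4.0), peak=np.ones(3)
    )
    _, flags = synthesize_waveform(decay, inst, gain=np.full(3, 100.0))
    assert "truncation_bias" in flags


def test_gain_is_a_pure_scale_factor(instrument):
    """Two noiseless records differing only in gain share one normalized
    decay shape after background subtraction."""
    from flimpipe.preprocess import subtract_background
    from flimpipe.synthetic import _background_template

    cfg = CohortConfig(
        phase="in_vivo", n_patients=1, n_mixed=1, n_healthy_only=0,
        points_per_class=4, target_snr_db=400.0, rng_seed=11,
        gain_ranges=((100.0, 100.0), (100.0, 100.0), (100.0, 100.0)),
    )
    cfg2 = CohortConfig(**{**cfg.__dict__, "gain_ranges": ((200.0, 200.0),) * 3})
    bg = _background_template(instrument, cfg)
    shapes = []
    for c in (cfg, cfg2):
        ws = generate_cohort(c, instrument).patients[0].waveforms
        clean = subtract_background(ws, (ws.gains / 100.0)[:, :, None] * bg[None])
        shapes.append(clean.samples / clean.samples.max(axis=-1, keepdims=True))
    np.testing.assert_allclose(shapes[0], shapes[1], atol=1e-9)


def test_no_signal_before_pulse_beyond_irf_support(small_cohort, instrument):
    """Baseline samples well before the pulse carry only noise/background."""
    ws = small_cohort.patients[0].waveforms
    n_pre = int((instrument.pulse_delay_ns - 3.0) / instrument.dt_raw_ns)
    pre = ws.samples[:, :, :n_pre]
    # pre-pulse level is far below the per-point peak
    assert np.abs(pre).max() < 0.1 * ws.samples.max()


def test_scan_points_spacing_follows_pulse_rate(small_cohort, instrument):
    """Along-row point spacing equals scan speed over pulse rate."""
    truth = small_cohort.patients[0].truth
    truth = truth[truth["label"] == truth["label"].iloc[0]]
    row = truth[np.isclose(truth["y_mm"], truth["y_mm"].iloc[0])]
    dx = np.diff(np.sort(row["x_mm"].to_numpy()))
    expected = small_cohort.config.scan_speed_mm_s / instrument.pulse_rate_hz
    np.testing.assert_allclose(dx, expected, rtol=1e-9)
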