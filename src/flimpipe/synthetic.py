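"""Synthetic FLIm cohort generator with known ground truth.

The clinical dataset this pipeline targets (hand-scanned oral-tumor FLIm
point measurements with histopathology labels) is not publicly available,
so every downstream stage is developed and validated against cohorts
produced here. The generator emulates the acquisition end to end:

* a cohort of 15 patients, 13 carrying both cancer and healthy tissue and
  2 carrying healthy tissue only;
* per-point, per-channel fluorescence decays (two-component exponential
  mixtures) convolved with a Gaussian instrument response, contaminated by
  a fiber-background template, scaled by detector gain, and sampled at
  2.5 GS/s with gain-dependent additive noise;
* a serpentine scan path sampled at the 115 Hz pulse rate, and a pathology
  label raster sharing the scan's physical (mm) coordinate frame.

Class separations are *calibrated*: each tissue model is built by solving
analytically for the cancer-class mean shift that yields a requested
Cohen's d (mean difference over within-subject SD) on a ground-truth
feature column. Recovery of those effect sizes by the weighted mixed-model
screen is the pipeline's principal end-to-end check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import erfcx

from .coregister import PathologyMask, LABEL_CODES
from .instrument import InstrumentModel
from .records import WaveformSet

__all__ = [
    "TissueModel",
    "CohortConfig",
    "PatientData",
    "Cohort",
    "preset_tissue_models",
    "calibrate_cancer_model",
    "generate_cohort",
    "synthesize_waveform",
    "DecayParams",
]

#: shape of the two-component decay mixture, scaled per point so that the
#: intensity-weighted first moment equals the point's true lifetime exactly.
#: amplitudes (0.6, 0.4) at relative lifetimes (0.5, 1.2906...) have unit
#: first moment: sum(a_i t_i^2) / sum(a_i t_i) = 1.
_SHAPE_AMP = np.array([0.6, 0.4])
_SHAPE_TAU = np.array([0.5, (0.4 + math.sqrt(0.16 + 0.24)) / 0.8])

#: reference lifetime (ns) for amplitude normalization in the forward model
_TAU_REF = 4.0


@dataclass(frozen=True)
class TissueModel:
    """Generative feature distribution for one tissue class.

    ``lifetime_mean``/``lifetime_sd`` are per-channel average-lifetime
    distributions (ns, within-subject). Spectral intensity is parameterized
    by the channel-3 (PpIX-band) fraction ``r3`` and the channel-1 share
    ``q`` of the remaining autofluorescence intensity, so intensity ratios
    are (1-r3)*q, (1-r3)*(1-q), r3 and sum to one by construction.

    ``target_effect_sizes`` records the Cohen's d values the class was
    calibrated to (empty for the healthy reference class).
    """

    tissue_class: str
    lifetime_mean: tuple[float, float, float]
    lifetime_sd: tuple[float, float, float]
    r3_mean: float
    r3_sd: float
    q_mean: float
    q_sd: float
    amplitude_scale: float = 2.0
    target_effect_sizes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(m <= 0 for m in self.lifetime_mean):
            raise ValueError("lifetime means must be positive")
        if not (0 < self.r3_mean < 1 and 0 < self.q_mean < 1):
            raise ValueError("intensity fractions must lie in (0, 1)")


def calibrate_cancer_model(
    healthy: TissueModel,
    d_lifetimes: tuple[float, float, float],
    d_ir3: float,
    d_q: float,
    tissue_class: str = "cancer",
) -> TissueModel:
    """Build a shifted tissue model hitting requested Cohen's d exactly.

    Cohen's d here is (cancer mean - healthy mean) / within-subject SD with
    the SD shared between classes, so the required mean shift is simply
    d * SD, solved analytically per feature.
    """
    means = tuple(
        m + d * s for m, d, s in zip(healthy.lifetime_mean, d_lifetimes, healthy.lifetime_sd)
    )
    return replace(
        healthy,
        tissue_class=tissue_class,
        lifetime_mean=means,
        r3_mean=healthy.r3_mean + d_ir3 * healthy.r3_sd,
        q_mean=healthy.q_mean + d_q * healthy.q_sd,
        target_effect_sizes={
            "lifetime_ch1": d_lifetimes[0],
            "lifetime_ch2": d_lifetimes[1],
            "lifetime_ch3": d_lifetimes[2],
            "ir_ch3": d_ir3,
        },
    )


def preset_tissue_models(phase: str) -> dict[str, TissueModel]:
    """Calibrated tissue models for the in vivo or ex vivo study phase.

    Healthy reference lifetimes sit in the few-ns autofluorescence range
    (collagen ~4 ns, NAD(P)H ~4.5 ns) with a long, heterogeneous PpIX band
    (~7 ns). Cancer models are calibrated to the headline per-phase effect
    sizes: in vivo the channel-1 lifetime (d = -0.74), channel-2 lifetime
    (-0.65) and channel-3 intensity ratio (+0.61); ex vivo the channel-2
    lifetime (-0.83), channel-3 intensity ratio (+1.0) and a depressed
    channel-1 autofluorescence share. Dysplasia is modeled midway between
    the two (only used when a dysplasia rim is enabled).
    """
    healthy = TissueModel(
        tissue_class="healthy",
        lifetime_mean=(4.0, 4.5, 7.0),
        lifetime_sd=(0.5, 0.5, 1.2),
        r3_mean=0.20,
        r3_sd=0.04,
        q_mean=0.55,
        q_sd=0.05,
    )
    if phase == "in_vivo":
        cancer = calibrate_cancer_model(
            healthy, d_lifetimes=(-0.74, -0.65, -0.05), d_ir3=0.61, d_q=0.50
        )
    elif phase == "ex_vivo":
        cancer = calibrate_cancer_model(
            healthy, d_lifetimes=(-0.20, -0.83, -0.10), d_ir3=1.00, d_q=-0.60
        )
    else:
        raise ValueError(f"unknown phase {phase!r} (expected 'in_vivo' or 'ex_vivo')")
    dysplasia = replace(
        cancer,
        tissue_class="dysplasia",
        lifetime_mean=tuple(
            0.5 * (h + c) for h, c in zip(healthy.lifetime_mean, cancer.lifetime_mean)
        ),
        r3_mean=0.5 * (healthy.r3_mean + cancer.r3_mean),
        q_mean=0.5 * (healthy.q_mean + cancer.q_mean),
        target_effect_sizes={},
    )
    return {"healthy": healthy, "cancer": cancer, "dysplasia": dysplasia}


@dataclass(frozen=True)
class CohortConfig:
    """Study-design and noise parameters for one generated cohort.

    The cohort mirrors the clinical study design: ``n_mixed`` patients carry
    both tissue classes, ``n_healthy_only`` carry healthy tissue only, and
    ``points_per_class`` decay measurements per class are spread across the
    cohort (cancer over the mixed patients, healthy over all patients).
    """

    phase: str = "in_vivo"
    n_patients: int = 15
    n_mixed: int = 13
    n_healthy_only: int = 2
    points_per_class: int = 20_000
    scan_speed_mm_s: float = 30.0
    row_pitch_mm: float = 0.5
    gain_ranges: tuple[tuple[float, float], ...] = ((20.0, 280.0), (100.0, 700.0), (100.0, 700.0))
    target_snr_db: float = 55.0
    gain_noise_knee: float = 300.0
    background_level: float = 0.10
    subject_lifetime_sd: tuple[float, float, float] = (0.30, 0.30, 0.80)
    subject_r3_sd: float = 0.02
    subject_q_sd: float = 0.03
    healthy_subregion_shift_ns: float = 0.0
    dysplasia_rim_mm: float = 0.0
    mask_pixel_mm: float = 0.1
    synthesize_waveforms: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mixed + self.n_healthy_only != self.n_patients:
            raise ValueError(
                f"n_mixed ({self.n_mixed}) + n_healthy_only ({self.n_healthy_only}) "
                f"must equal n_patients ({self.n_patients})"
            )
        if self.points_per_class <= 0:
            raise ValueError("points_per_class must be positive")
        if self.scan_speed_mm_s <= 0:
            raise ValueError("scan_speed_mm_s must be positive")
        if len(self.gain_ranges) != 3:
            raise ValueError("one gain range per channel required")


@dataclass
class PatientData:
    """One generated patient scan: waveforms (optional), mask, and truth."""

    patient_id: str
    phase: str
    waveforms: WaveformSet | None
    mask: PathologyMask
    truth: pd.DataFrame


@dataclass
class Cohort:
    config: CohortConfig
    patients: list[PatientData]

    @property
    def truth(self) -> pd.DataFrame:
        """Cohort-wide ground-truth feature table (one row per point)."""
        return pd.concat([p.truth for p in self.patients], ignore_index=True)


# ---------------------------------------------------------------------------
# waveform forward model


@dataclass(frozen=True)
class DecayParams:
    """True decay of one point: per-channel (amplitudes, lifetimes ns) and
    per-channel peak amplitude (after gain)."""

    amplitudes: np.ndarray  # (3, n_components)
    lifetimes_ns: np.ndarray  # (3, n_components)
    peak: np.ndarray  # (3,)


def _gaussian_exp_conv(t_ns: np.ndarray, tau_ns: np.ndarray, t0_ns: float, sigma_ns: float) -> np.ndarray:
    """Convolution of a unit-amplitude causal exponential with a unit-area
    Gaussian IRF, evaluated in closed form (exponentially modified Gaussian).

    Broadcasts over leading axes of ``tau_ns``; ``t_ns`` indexes the last
    axis. Stable for sigma << tau via the scaled complementary error
    function; falls back to the bare exponential where the Gaussian factor
    has fully decayed.
    """
    delta = t_ns - t0_ns
    tau = np.asarray(tau_ns)[..., None]
    if sigma_ns <= 0:
        return np.where(delta >= 0, np.exp(-np.clip(delta, 0, None) / tau), 0.0)
    b = (sigma_ns / tau - delta / sigma_ns) / math.sqrt(2.0)
    # exp(s^2/2t^2 - d/t) * erfc(b) / 2 == exp(-d^2/2s^2) * erfcx(b) / 2
    safe = b > -25.0
    out = np.empty(np.broadcast_shapes(tau.shape, np.shape(delta)), dtype=float)
    with np.errstate(over="ignore", under="ignore"):
        core = 0.5 * np.exp(-0.5 * (delta / sigma_ns) ** 2) * erfcx(np.where(safe, b, 0.0))
        tail = np.exp((sigma_ns**2) / (2.0 * tau**2) - delta / tau)
    np.copyto(out, np.where(safe, core, tail))
    return out


def _forward_convolve(
    amplitudes: np.ndarray, lifetimes_ns: np.ndarray, instrument: InstrumentModel
) -> np.ndarray:
    """Discrete forward model on the raw grid.

    The multi-exponential decay is sampled on the fine (upsampled)
    processing grid, convolved discretely with the digitized system IRF on
    that grid, and decimated to the 2.5 GS/s record — exactly the model the
    Laguerre deconvolution inverts after preprocessing re-interpolates the
    record, so noiseless round trips are exact up to interpolation error.

    ``amplitudes`` and ``lifetimes_ns`` have shape (n, 3, n_components);
    returns (n, 3, n_samples_raw) with per-point peak ~ sum(amplitudes).
    """
    from scipy.signal import fftconvolve

    t_up = instrument.time_axis_ns(upsampled=True)
    irf_up = instrument.irf(upsampled=True)
    factor = instrument.upsample_factor
    with np.errstate(under="ignore"):
        decay = np.einsum(
            "nkc,nkct->nkt",
            amplitudes,
            np.exp(-t_up[None, None, None, :] / lifetimes_ns[..., None]),
        )
    fine = fftconvolve(decay, irf_up[None, None, :], mode="full", axes=-1)[..., : len(t_up)]
    return fine[..., ::factor]


def synthesize_waveform(
    decay: DecayParams,
    instrument: InstrumentModel,
    gain: np.ndarray,
    rng: np.random.Generator | None = None,
    noise_sd: np.ndarray | None = None,
    background_scale: np.ndarray | None = None,
) -> tuple[np.ndarray, set[str]]:
    """Forward-model one point measurement on the raw 2.5 GS/s grid.

    Returns ``(samples, flags)`` with ``samples`` of shape (3, n_raw):
    multi-exponential decay convolved with the Gaussian IRF, peak-scaled,
    plus the scaled fiber-background template and additive Gaussian noise.
    A ``truncation_bias`` flag is raised when the post-pulse window is
    shorter than ~3x the longest lifetime.
    """
    flags: set[str] = set()
    shape = _forward_convolve(decay.amplitudes[None], decay.lifetimes_ns[None], instrument)[0]
    norm = decay.amplitudes.sum(axis=1, keepdims=True)
    samples = decay.peak[:, None] * shape / norm
    if background_scale is not None and instrument.background_waveform is not None:
        samples = samples + background_scale[:, None] * instrument.background_waveform
    if noise_sd is not None and rng is not None:
        samples = samples + rng.normal(0.0, 1.0, samples.shape) * np.asarray(noise_sd)[:, None]
    if (instrument.window_ns - instrument.pulse_delay_ns) < 3.0 * decay.lifetimes_ns.max():
        flags.add("truncation_bias")
    if np.any(np.asarray(gain) <= 0):
        raise ValueError("gain must be positive")
    return samples, flags


def _noise_sd(peak: np.ndarray, gain: np.ndarray, config: CohortConfig) -> np.ndarray:
    """Additive-noise SD: peak / SNR, amplified above the gain knee."""
    base = peak / 10.0 ** (config.target_snr_db / 20.0)
    excess = 1.0 + np.clip((gain - config.gain_noise_knee) / config.gain_noise_knee, 0.0, None) ** 1.5
    return base * excess


# ---------------------------------------------------------------------------
# scan geometry


def _serpentine_path(
    n_points: int, x0: float, x1: float, speed: float, pulse_rate: float, row_pitch: float, margin: float
) -> np.ndarray:
    """(n, 2) point positions along a serpentine scan of region [x0, x1) x y.

    Point spacing along a row is scan speed over pulse rate; rows are
    ``row_pitch`` apart. The path stays ``margin`` away from the region's
    x-extent so raster lookups are unambiguous.
    """
    dx = speed / pulse_rate
    xs = np.arange(x0 + margin, x1 - margin, dx)
    if len(xs) == 0:
        xs = np.array([0.5 * (x0 + x1)])
    per_row = len(xs)
    n_rows = int(math.ceil(n_points / per_row))
    pts = np.empty((n_points, 2))
    k = 0
    for r in range(n_rows):
        row_x = xs if r % 2 == 0 else xs[::-1]
        take = min(per_row, n_points - k)
        pts[k : k + take, 0] = row_x[:take]
        pts[k : k + take, 1] = row_pitch * (r + 0.5)
        k += take
    return pts


def _patient_mask(
    config: CohortConfig, mixed: bool, height_mm: float, field_mm: float, boundary_mm: float
) -> PathologyMask:
    px = config.mask_pixel_mm
    nx = int(round(field_mm / px))
    ny = max(int(math.ceil(height_mm / px)), 1)
    raster = np.full((ny, nx), LABEL_CODES["healthy"], dtype=np.uint8)
    if mixed:
        xb = int(round(boundary_mm / px))
        raster[:, :xb] = LABEL_CODES["cancer"]
        rim = int(round(config.dysplasia_rim_mm / px))
        if rim > 0:
            raster[:, xb : xb + rim] = LABEL_CODES["dysplasia"]
    return PathologyMask(label_raster=raster, pixel_size_mm=px, origin_mm=(0.0, 0.0))


# ---------------------------------------------------------------------------
# cohort generation


def _split_counts(total: int, n_bins: int) -> list[int]:
    base, rem = divmod(total, n_bins)
    return [base + (1 if i < rem else 0) for i in range(n_bins)]


def generate_cohort(
    config: CohortConfig,
    instrument: InstrumentModel | None = None,
    tissue_models: dict[str, TissueModel] | None = None,
) -> Cohort:
    """Generate a full synthetic cohort: scans, masks, and ground truth.

    Deterministic given ``config.rng_seed``. Mixed patients hold both a
    cancer and a healthy region (cancer at x < boundary); healthy-only
    patients hold a single healthy region. Every point carries its true
    per-channel lifetime, intensity ratios, gains, and tissue label in the
    patient's ``truth`` table.
    """
    if instrument is None:
        instrument = InstrumentModel()
    if tissue_models is None:
        tissue_models = preset_tissue_models(config.phase)
    for cls in ("cancer", "healthy"):
        if cls not in tissue_models:
            raise ValueError(f"missing tissue model for class {cls!r}")

    rng = np.random.default_rng(config.rng_seed)
    region_w = 10.0  # mm; per-region scan width
    boundary = region_w
    field_w = 2.0 * region_w

    cancer_counts = _split_counts(config.points_per_class, config.n_mixed)
    healthy_counts = _split_counts(config.points_per_class, config.n_patients)

    bg = _background_template(instrument, config)
    instrument = replace(instrument, background_waveform=bg if config.synthesize_waveforms else None)

    patients: list[PatientData] = []
    point_counter = 0
    for i in range(config.n_patients):
        pid = f"P{i + 1:02d}"
        mixed = i < config.n_mixed
        # per-subject random intercepts, shared across tissue classes
        subj_tau = rng.normal(0.0, config.subject_lifetime_sd)
        subj_r3 = rng.normal(0.0, config.subject_r3_sd)
        subj_q = rng.normal(0.0, config.subject_q_sd)

        regions: list[tuple[str, int, float, float]] = []
        if mixed:
            regions.append(("cancer", cancer_counts[i], 0.0, boundary))
        regions.append(("healthy", healthy_counts[i], boundary if mixed else 0.0, field_w if mixed else region_w))

        frames = []
        max_height = 0.0
        for cls, n_pts, rx0, rx1 in regions:
            if n_pts == 0:
                continue
            model = tissue_models[cls]
            xy = _serpentine_path(
                n_pts, rx0, rx1, config.scan_speed_mm_s, instrument.pulse_rate_hz,
                config.row_pitch_mm, margin=2.0 * config.mask_pixel_mm,
            )
            max_height = max(max_height, xy[:, 1].max() + config.row_pitch_mm)
            tau = np.stack(
                [
                    np.clip(model.lifetime_mean[k] + subj_tau[k]
                            + rng.normal(0.0, model.lifetime_sd[k], n_pts), 0.2, None)
                    for k in range(3)
                ],
                axis=1,
            )
            if cls == "healthy" and config.healthy_subregion_shift_ns != 0.0:
                # optional gingiva-vs-mucosa heterogeneity: half the healthy
                # points get a channel-3 lifetime offset
                half = rng.random(n_pts) < 0.5
                tau[half, 2] += config.healthy_subregion_shift_ns
            r3 = np.clip(model.r3_mean + subj_r3 + rng.normal(0.0, model.r3_sd, n_pts), 0.02, 0.90)
            q = np.clip(model.q_mean + subj_q + rng.normal(0.0, model.q_sd, n_pts), 0.05, 0.95)
            ir = np.stack([(1.0 - r3) * q, (1.0 - r3) * (1.0 - q), r3], axis=1)
            gains = np.stack(
                [rng.uniform(lo, hi, n_pts) for (lo, hi) in config.gain_ranges], axis=1
            )
            frames.append(
                pd.DataFrame(
                    {
                        "point_id": np.arange(point_counter, point_counter + n_pts),
                        "patient_id": pid,
                        "phase": config.phase,
                        "label": cls,
                        "x_mm": xy[:, 0],
                        "y_mm": xy[:, 1],
                        "true_lifetime_ch1": tau[:, 0],
                        "true_lifetime_ch2": tau[:, 1],
                        "true_lifetime_ch3": tau[:, 2],
                        "true_ir_ch1": ir[:, 0],
                        "true_ir_ch2": ir[:, 1],
                        "true_ir_ch3": ir[:, 2],
                        "gain_ch1": gains[:, 0],
                        "gain_ch2": gains[:, 1],
                        "gain_ch3": gains[:, 2],
                    }
                )
            )
            point_counter += n_pts
        truth = pd.concat(frames, ignore_index=True)
        mask = _patient_mask(config, mixed, max_height, field_w if mixed else region_w, boundary)

        waveforms = None
        if config.synthesize_waveforms:
            waveforms = _synthesize_patient(truth, instrument, config, rng, pid)
        patients.append(PatientData(pid, config.phase, waveforms, mask, truth))

    return Cohort(config=config, patients=patients)


def _background_template(instrument: InstrumentModel, config: CohortConfig) -> np.ndarray:
    """Fiber-fluorescence template per channel at reference gain 100: a fast
    (1.8 ns) decay launched at the pulse time, peak = background_level."""
    amps = np.ones((1, 3, 1))
    taus = np.full((1, 3, 1), 1.8)
    shape = _forward_convolve(amps, taus, instrument)[0, 0]
    levels = np.array([1.0, 0.8, 0.5]) * config.background_level
    return levels[:, None] * shape[None, :]


def _synthesize_patient(
    truth: pd.DataFrame,
    instrument: InstrumentModel,
    config: CohortConfig,
    rng: np.random.Generator,
    patient_id: str,
) -> WaveformSet:
    n = len(truth)
    n_raw = instrument.n_samples_raw
    tau_pts = truth[[f"true_lifetime_ch{k}" for k in (1, 2, 3)]].to_numpy()  # (n, 3)
    ir = truth[[f"true_ir_ch{k}" for k in (1, 2, 3)]].to_numpy()
    gains = truth[[f"gain_ch{k}" for k in (1, 2, 3)]].to_numpy()
    amp_scale = 2.0  # a.u. brightness at reference gain and unit fraction

    samples = np.empty((n, 3, n_raw))
    # amplitude ~ ir / tau so the *integrated* channel intensity fraction
    # (what the pipeline measures, after gain correction) equals the true
    # intensity ratio
    peaks = amp_scale * ir * (_TAU_REF / tau_pts) * gains / 100.0  # (n, 3)
    amps = np.broadcast_to(_SHAPE_AMP, (n, 3, len(_SHAPE_AMP)))
    taus = tau_pts[:, :, None] * _SHAPE_TAU
    chunk = 512  # bound fine-grid memory for large cohorts
    for lo in range(0, n, chunk):
        hi = min(lo + chunk, n)
        samples[lo:hi] = _forward_convolve(amps[lo:hi], taus[lo:hi], instrument)
    samples *= peaks[:, :, None]
    if instrument.background_waveform is not None:
        samples += (gains / 100.0)[:, :, None] * instrument.background_waveform[None, :, :]
    noise = _noise_sd(peaks, gains, config)
    samples += rng.normal(0.0, 1.0, samples.shape) * noise[:, :, None]

    flags = [set() for _ in range(n)]
    horizon = instrument.window_ns - instrument.pulse_delay_ns
    for idx in np.nonzero(tau_pts.max(axis=1) * 3.0 > horizon)[0]:
        flags[idx].add("truncation_bias")
    return WaveformSet(
        samples=samples,
        gains=gains,
        xy_mm=truth[["x_mm", "y_mm"]].to_numpy(),
        point_ids=truth["point_id"].to_numpy(),
        patient_id=patient_id,
        phase=config.phase,
        sample_rate=instrument.sample_rate_raw,
        flags=flags,
    )
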