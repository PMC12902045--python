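"""Instrument model for a fiber-based pulse-sampling FLIm system.

The system excites tissue with a pulsed UV laser (sub-60 ps FWHM, 115 Hz
repetition rate) and records the fluorescence decay of each pulse on three
spectrally resolved channels with variable-gain avalanche photodiodes,
digitized at 2.5 GS/s. Decays are later upsampled to 12.5 GS/s for
processing. This module holds the static description of that hardware:
timing, spectral bands, excitation-spot geometry, and the fiber-background
template, plus small utilities derived from them (time grids, the Gaussian
instrument response, and the Nyquist scanning-speed rule).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ChannelSpec",
    "InstrumentModel",
    "default_channels",
    "default_instrument",
    "nyquist_scan_speed",
]


@dataclass(frozen=True)
class ChannelSpec:
    """One spectral detection channel.

    Parameters
    ----------
    index
        Channel number, 1-based (1, 2 or 3).
    center_nm, band_nm
        Center wavelength and full bandwidth of the emission filter.
    fluorophore_role
        Dominant fluorophore in the band (collagen, NAD(P)H or PpIX).
    gain_keep_low, gain_keep_high
        Detector-gain keep-range for quality filtering. ``gain_keep_low``
        may be ``None`` (no lower bound).
    """

    index: int
    center_nm: float
    band_nm: float
    fluorophore_role: str
    gain_keep_low: float | None
    gain_keep_high: float

    def __post_init__(self) -> None:
        if self.index not in (1, 2, 3):
            raise ValueError(f"channel index must be 1, 2 or 3, got {self.index}")
        if self.gain_keep_low is not None and not (self.gain_keep_low < self.gain_keep_high):
            raise ValueError("gain keep-range must satisfy low < high")


def default_channels() -> tuple[ChannelSpec, ChannelSpec, ChannelSpec]:
    """The three emission bands with their default gain keep-ranges.

    Channel 1 (390/40 nm) targets collagen, channel 2 (470/28 nm) NAD(P)H,
    channel 3 (629/53 nm) protoporphyrin IX. Gain keep-ranges are the
    calibrated defaults: (15, 300) for channel 1 and an upper bound of 800
    for channels 2 and 3.
    """
    return (
        ChannelSpec(1, 390.0, 40.0, "collagen", 15.0, 300.0),
        ChannelSpec(2, 470.0, 28.0, "NAD(P)H", None, 800.0),
        ChannelSpec(3, 629.0, 53.0, "PpIX", None, 800.0),
    )


@dataclass(frozen=True)
class InstrumentModel:
    """Timing and geometry of the FLIm acquisition chain.

    Attributes
    ----------
    irf_fwhm_ps
        Full width at half maximum of the (Gaussian) excitation pulse, ps.
    detector_fwhm_ns
        FWHM of the detection chain's impulse response (APD + amplifier +
        digitizer front end), ns. The *system* IRF used for synthesis and
        deconvolution is the convolution of pulse and detector responses;
        the detector dominates and keeps the recorded waveform band-limited
        at the raw sampling rate.
    sample_rate_raw, sample_rate_up
        Digitizer rate and processing (upsampled) rate, samples/s. The
        upsampled rate must be an integer multiple of the raw rate.
    pulse_rate_hz
        Laser repetition / point-measurement rate, Hz.
    window_ns
        Length of the digitized decay window per pulse, ns. Must hold a
        whole number of raw samples.
    pulse_delay_ns
        Arrival time of the excitation pulse within the window (leaves a
        pre-pulse baseline segment for noise estimation).
    background_waveform
        Per-channel fiber-fluorescence template on the raw grid, shape
        (3, n_samples_raw), unit peak amplitude; all zeros when absent.
    lateral_resolution_mm
        Diameter of the excited tissue spot (~0.5 mm).
    depth_of_field_um
        Depth of excitation (informational, 250-300 um).
    """

    irf_fwhm_ps: float = 60.0
    detector_fwhm_ns: float = 0.8
    sample_rate_raw: float = 2.5e9
    sample_rate_up: float = 12.5e9
    pulse_rate_hz: float = 115.0
    window_ns: float = 80.0
    pulse_delay_ns: float = 8.0
    background_waveform: np.ndarray | None = None
    lateral_resolution_mm: float = 0.5
    depth_of_field_um: float = 275.0
    channels: tuple[ChannelSpec, ...] = field(default_factory=default_channels)

    def __post_init__(self) -> None:
        if self.irf_fwhm_ps <= 0:
            raise ValueError("irf_fwhm_ps must be positive")
        ratio = self.sample_rate_up / self.sample_rate_raw
        if abs(ratio - round(ratio)) > 1e-9 or round(ratio) < 1:
            raise ValueError("sample_rate_up must be an integer multiple of sample_rate_raw")
        n = self.window_ns * 1e-9 * self.sample_rate_raw
        if abs(n - round(n)) > 1e-6:
            raise ValueError("window_ns must hold a whole number of raw samples")
        if not (0 <= self.pulse_delay_ns < self.window_ns):
            raise ValueError("pulse_delay_ns must lie inside the window")
        if len(self.channels) != 3:
            raise ValueError("exactly 3 channels required")

    # -- derived quantities -------------------------------------------------

    @property
    def n_samples_raw(self) -> int:
        return int(round(self.window_ns * 1e-9 * self.sample_rate_raw))

    @property
    def n_samples_up(self) -> int:
        return self.n_samples_raw * self.upsample_factor

    @property
    def upsample_factor(self) -> int:
        return int(round(self.sample_rate_up / self.sample_rate_raw))

    @property
    def dt_raw_ns(self) -> float:
        return 1e9 / self.sample_rate_raw

    @property
    def dt_up_ns(self) -> float:
        return 1e9 / self.sample_rate_up

    def time_axis_ns(self, upsampled: bool = False) -> np.ndarray:
        """Sample times in ns, 0 at the start of the digitized window."""
        if upsampled:
            return np.arange(self.n_samples_up) * self.dt_up_ns
        return np.arange(self.n_samples_raw) * self.dt_raw_ns

    @property
    def system_irf_sigma_ns(self) -> float:
        """Gaussian SD of the system response: pulse convolved with detector."""
        to_sigma = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        s_pulse = self.irf_fwhm_ps * 1e-3 * to_sigma
        s_det = self.detector_fwhm_ns * to_sigma
        return float(np.hypot(s_pulse, s_det))

    def irf(self, upsampled: bool = True) -> np.ndarray:
        """Unit-sum Gaussian system IRF centered at ``pulse_delay_ns``."""
        t = self.time_axis_ns(upsampled=upsampled)
        sigma = max(self.system_irf_sigma_ns, 1e-6)
        g = np.exp(-0.5 * ((t - self.pulse_delay_ns) / sigma) ** 2)
        return g / g.sum()

    def nyquist_scan_speed(self) -> float:
        """Maximum scan speed (mm/s) that still satisfies Nyquist sampling."""
        return nyquist_scan_speed(self.pulse_rate_hz, self.lateral_resolution_mm)


def nyquist_scan_speed(pulse_rate_hz: float, lateral_resolution_mm: float) -> float:
    """Nyquist-limited scan speed: 1/2 x measurement rate x lateral resolution.

    With the default 115 Hz point rate and 0.5 mm excitation spot this is
    28.75 mm/s; hand scanning slower than this oversamples the tissue along
    the scan path.
    """
    if pulse_rate_hz <= 0 or lateral_resolution_mm <= 0:
        raise ValueError("pulse rate and lateral resolution must be positive")
    return 0.5 * pulse_rate_hz * lateral_resolution_mm
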