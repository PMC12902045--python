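"""In-memory container for batches of pulse-sampled waveform records."""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["WaveformSet"]


@dataclass
class WaveformSet:
    """A scan's worth of per-pulse decay waveforms.

    One row per point measurement; three spectral channels per point.

    Attributes
    ----------
    samples
        Raw (or preprocessed) amplitude series, shape (n_points, 3, n_samples).
    gains
        Detector gain per point and channel, shape (n_points, 3).
    xy_mm
        Scan position per point in mm, shape (n_points, 2).
    point_ids
        Integer point identifiers, shape (n_points,).
    patient_id, phase
        Scan provenance; ``phase`` is ``"in_vivo"`` or ``"ex_vivo"``.
    sample_rate
        Samples per second of the current ``samples`` grid.
    flags
        Per-point set of quality flags.
    """

    samples: np.ndarray
    gains: np.ndarray
    xy_mm: np.ndarray
    point_ids: np.ndarray
    patient_id: str
    phase: str
    sample_rate: float
    flags: list[set] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 3 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n_points, 3, n_samples)")
        n = self.samples.shape[0]
        self.gains = np.asarray(self.gains, dtype=float)
        if self.gains.shape != (n, 3):
            raise ValueError("gains must have shape (n_points, 3)")
        if np.any(self.gains <= 0):
            raise ValueError("gains must be positive")
        if not self.flags:
            self.flags = [set() for _ in range(n)]
        if len(self.flags) != n:
            raise ValueError("one flag set per point required")

    @property
    def n_points(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[2]

    @property
    def dt_ns(self) -> float:
        return 1e9 / self.sample_rate

    def select(self, index: np.ndarray) -> "WaveformSet":
        """Row subset (boolean mask or integer index), flags carried along."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.nonzero(idx)[0]
        return replace(
            self,
            samples=self.samples[idx],
            gains=self.gains[idx],
            xy_mm=self.xy_mm[idx],
            point_ids=self.point_ids[idx],
            flags=[set(self.flags[i]) for i in idx],
        )
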