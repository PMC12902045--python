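"""Pathology co-registration: raster label lookup with exclusion rules.

Histopathology annotations arrive as an integer-coded 2D label raster (plus
a JSON legend) sharing the scan's physical coordinate frame. Each FLIm
point is assigned the label of the pixel it falls in. Points whose labels
are unreliable are excluded rather than guessed:

* points outside the raster or on unlabeled pixels;
* points within a configurable buffer of the cancer-healthy interface,
  where region-level labels are most prone to registration error;
* dysplasia pixels (excluded by default; optionally folded into the
  non-cancer class, since the downstream analysis is binary).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = ["LABEL_CODES", "LABEL_NAMES", "PathologyMask", "assign_labels", "label_summary"]

LABEL_CODES = {"unlabeled": 0, "healthy": 1, "cancer": 2, "dysplasia": 3}
LABEL_NAMES = {v: k for k, v in LABEL_CODES.items()}

EXCLUSION_REASONS = ("none", "unlabeled", "interface_buffer", "dysplasia", "ambiguous")


@dataclass(frozen=True)
class PathologyMask:
    """Integer label raster with physical-units geometry.

    ``label_raster[iy, ix]`` covers the half-open physical cell
    ``[origin + i*pixel, origin + (i+1)*pixel)`` in mm, x along columns and
    y along rows, so lookups are bit-exact on generated data.
    """

    label_raster: np.ndarray
    pixel_size_mm: float
    origin_mm: tuple[float, float] = (0.0, 0.0)
    legend: dict = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.pixel_size_mm <= 0:
            raise ValueError("pixel_size_mm must be positive")
        raster = np.asarray(self.label_raster)
        if raster.ndim != 2:
            raise ValueError("label_raster must be 2D")
        legend = self.legend if self.legend is not None else dict(LABEL_NAMES)
        unknown = set(np.unique(raster)) - set(legend)
        if unknown:
            raise ValueError(f"raster codes missing from legend: {sorted(unknown)}")
        object.__setattr__(self, "legend", legend)

    def pixel_index(self, xy_mm: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(ix, iy, inside) for each point; half-open pixel intervals."""
        xy = np.atleast_2d(np.asarray(xy_mm, dtype=float))
        ix = np.floor((xy[:, 0] - self.origin_mm[0]) / self.pixel_size_mm).astype(int)
        iy = np.floor((xy[:, 1] - self.origin_mm[1]) / self.pixel_size_mm).astype(int)
        ny, nx = self.label_raster.shape
        inside = (ix >= 0) & (ix < nx) & (iy >= 0) & (iy < ny)
        return ix, iy, inside


def _interface_distance_mm(mask: PathologyMask) -> np.ndarray:
    """Per-pixel distance (mm, between pixel centers) to the nearest pixel
    of the opposite class across the cancer-healthy interface. Pixels of
    classes not part of the interface get +inf."""
    raster = mask.label_raster
    cancer = raster == LABEL_CODES["cancer"]
    healthy = raster == LABEL_CODES["healthy"]
    dist = np.full(raster.shape, np.inf)
    if cancer.any() and healthy.any():
        d_to_cancer = ndimage.distance_transform_edt(~cancer) * mask.pixel_size_mm
        d_to_healthy = ndimage.distance_transform_edt(~healthy) * mask.pixel_size_mm
        dist[healthy] = d_to_cancer[healthy]
        dist[cancer] = d_to_healthy[cancer]
    return dist


def assign_labels(
    xy_mm: np.ndarray,
    mask: PathologyMask,
    buffer_mm: float = 0.5,
    dysplasia_as_noncancer: bool = False,
) -> pd.DataFrame:
    """Label each point by raster lookup, recording exclusions.

    Returns a DataFrame with columns ``label`` (``cancer``/``healthy``/empty),
    ``excluded`` and ``exclusion_reason``, aligned with the input points.
    The output is binary: dysplasia pixels are either excluded (default) or
    mapped to the non-cancer class. Points within ``buffer_mm`` of the
    cancer-healthy interface are excluded as mislabel-prone.
    """
    xy = np.atleast_2d(np.asarray(xy_mm, dtype=float))
    n = len(xy)
    ix, iy, inside = mask.pixel_index(xy)
    codes = np.full(n, LABEL_CODES["unlabeled"], dtype=int)
    codes[inside] = mask.label_raster[iy[inside], ix[inside]]

    label = np.full(n, "", dtype=object)
    reason = np.full(n, "none", dtype=object)

    reason[codes == LABEL_CODES["unlabeled"]] = "unlabeled"
    if dysplasia_as_noncancer:
        codes = np.where(codes == LABEL_CODES["dysplasia"], LABEL_CODES["healthy"], codes)
    else:
        reason[codes == LABEL_CODES["dysplasia"]] = "dysplasia"

    if buffer_mm > 0:
        dist = _interface_distance_mm(mask)
        near = np.zeros(n, dtype=bool)
        near[inside] = dist[iy[inside], ix[inside]] < buffer_mm
        near &= reason == "none"
        reason[near] = "interface_buffer"

    keep = reason == "none"
    label[keep & (codes == LABEL_CODES["cancer"])] = "cancer"
    label[keep & (codes == LABEL_CODES["healthy"])] = "healthy"

    return pd.DataFrame(
        {
            "label": label,
            "excluded": reason != "none",
            "exclusion_reason": pd.Categorical(reason, categories=list(EXCLUSION_REASONS)),
        }
    )


def label_summary(labeled: pd.DataFrame, by: str | None = "patient_id") -> pd.DataFrame:
    """Per-patient (and cohort) accounting of labeled vs excluded points.

    ``labeled`` must carry ``label``, ``excluded``, ``exclusion_reason`` and,
    when ``by`` is given, that grouping column. Counts conserve the input
    total; a ``cohort`` row holds the rollup.
    """
    df = labeled.copy()
    groups = [by] if by and by in df.columns else []

    def _counts(g: pd.DataFrame) -> pd.Series:
        out = {
            "n_points": len(g),
            "n_cancer": int((g["label"] == "cancer").sum()),
            "n_healthy": int((g["label"] == "healthy").sum()),
            "n_excluded": int(g["excluded"].sum()),
        }
        for r in EXCLUSION_REASONS[1:]:
            out[f"excluded_{r}"] = int((g["exclusion_reason"] == r).sum())
        return pd.Series(out)

    if groups:
        table = df.groupby(groups[0], observed=True).apply(_counts, include_groups=False).reset_index()
    else:
        table = _counts(df).to_frame().T
        table.insert(0, "patient_id", "all")
    rollup = _counts(df).to_frame().T
    rollup.insert(0, table.columns[0], "cohort")
    return pd.concat([table, rollup], ignore_index=True)
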