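"""Feature transforms: skew correction and standardization.

Highly skewed feature columns get a square-root transform (after shifting
so the minimum is zero); every analyzed column is then standardized to
zero mean and unit SD. Both the skewness criterion and the moments use the
analysis weights, so transform decisions are not dominated by
over-represented patients. A transform log records every per-column
decision and constant so the chain is auditable and reproducible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["weighted_skewness", "transform_features"]


def weighted_skewness(x: np.ndarray, w: np.ndarray) -> float:
    """Weight-adjusted sample skewness (third standardized moment)."""
    w = w / w.sum()
    mu = float(np.sum(w * x))
    var = float(np.sum(w * (x - mu) ** 2))
    if var <= 0:
        return 0.0
    return float(np.sum(w * (x - mu) ** 3) / var**1.5)


def transform_features(
    table: pd.DataFrame,
    feature_cols: list[str],
    weights: np.ndarray | None = None,
    skew_threshold: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transform feature columns in place-order: sqrt for skewed, then z-score.

    Rows must already be free of missing values in ``feature_cols``.
    Returns ``(transformed table, log)`` where the log has one row per
    column: whether sqrt was applied, the shift constant, the skewness, and
    the standardization mean/SD. Zero-variance columns are flagged and left
    unstandardized.
    """
    out = table.copy()
    w = np.ones(len(table)) if weights is None else np.asarray(weights, dtype=float)
    log_rows = []
    for col in feature_cols:
        x = out[col].to_numpy(dtype=float)
        if not np.isfinite(x).all():
            raise ValueError(f"column {col!r} contains missing values; drop them first")
        skew = weighted_skewness(x, w)
        shift = 0.0
        sqrt_applied = abs(skew) > skew_threshold
        if sqrt_applied:
            # reflect left-skewed columns so the sqrt compresses the long tail
            if skew < 0:
                x = -x
            shift = -float(x.min())
            x = np.sqrt(x + shift)
        wn = w / w.sum()
        mu = float(np.sum(wn * x))
        sd = float(np.sqrt(np.sum(wn * (x - mu) ** 2)))
        degenerate = sd <= 1e-12
        if not degenerate:
            x = (x - mu) / sd
        out[col] = x
        log_rows.append(
            {
                "feature": col,
                "skewness": skew,
                "sqrt_applied": sqrt_applied,
                "reflected": sqrt_applied and skew < 0,
                "shift": shift,
                "mean": mu,
                "sd": sd,
                "zero_variance": degenerate,
            }
        )
    return out, pd.DataFrame(log_rows)
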