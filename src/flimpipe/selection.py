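"""Collinearity diagnostics and backward model selection.

The multivariable weighted logistic mixed model starts from all intensity
ratios, lifetimes, and the between-/within-subject PCs, then is pruned in
two phases: first the predictor with the largest variance inflation
factor is removed (one at a time) while any VIF exceeds the threshold
(VIF > 10 marks serious multicollinearity); then the largest-p predictor
is removed (one at a time, refitting) while any p-value exceeds the
significance threshold. Each removal is recorded in an audit trail with
its triggering value, so the selection path can be reconstructed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .logisticmm import LogisticMMResult, fit_weighted_logistic_mixed

__all__ = ["vif", "backward_select", "SelectionResult"]


def vif(X: pd.DataFrame, weights: np.ndarray | None = None) -> pd.Series:
    """Variance inflation factors, VIF_j = 1 / (1 - R^2_j).

    R^2_j is the (weighted) coefficient of determination of predictor j
    regressed on an intercept plus all other predictors. Perfect
    collinearity is reported as +inf.
    """
    cols = list(X.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 predictors for VIF")
    Xa = X.to_numpy(dtype=float)
    n = Xa.shape[0]
    if n < len(cols):
        raise ValueError("need at least as many rows as predictors")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    out = {}
    for j, col in enumerate(cols):
        yj = Xa[:, j]
        others = np.column_stack([np.ones(n), np.delete(Xa, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others * sw[:, None], yj * sw, rcond=None)
        resid = yj - others @ coef
        ybar = np.sum(w * yj) / w.sum()
        sst = float(np.sum(w * (yj - ybar) ** 2))
        ssr = float(np.sum(w * resid**2))
        if sst <= 0:
            out[col] = np.inf
            continue
        r2 = 1.0 - ssr / sst
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


@dataclass
class SelectionResult:
    """Final model after backward selection, with the removal audit trail."""

    model: LogisticMMResult | None
    retained: list[str]
    audit_trail: list[dict] = field(default_factory=list)
    flags: set = field(default_factory=set)

    def audit_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.audit_trail)


def backward_select(
    y: np.ndarray,
    X: pd.DataFrame,
    subjects: np.ndarray,
    weights: np.ndarray | None = None,
    vif_threshold: float = 10.0,
    p_threshold: float = 0.05,
) -> SelectionResult:
    """VIF-then-p backward selection of the weighted logistic mixed model.

    ``X`` holds the candidate predictors (no intercept column; one is added
    to every fit and never removed). Ties on the removal criterion are
    broken deterministically by column order. Terminates in at most one
    removal per predictor; if everything is removed, an empty-model result
    is returned flagged ``all_removed``.
    """
    predictors = list(X.columns)
    audit: list[dict] = []

    # phase 1: resolve multicollinearity
    while len(predictors) >= 2:
        v = vif(X[predictors], weights)
        worst = v.idxmax()
        if not (v[worst] > vif_threshold):
            break
        audit.append(
            {"phase": "vif", "removed": worst, "value": float(v[worst]),
             "criterion": f"VIF > {vif_threshold}"}
        )
        predictors.remove(worst)

    # phase 2: prune non-significant predictors, refitting each time
    def _fit(preds: list[str]) -> LogisticMMResult:
        design = X[preds].copy()
        design.insert(0, "intercept", 1.0)
        return fit_weighted_logistic_mixed(y, design, subjects, weights)

    model = None
    while predictors:
        model = _fit(predictors)
        pv = model.pvalues.drop("intercept")
        worst = pv.idxmax()
        if not (pv[worst] > p_threshold):
            break
        audit.append(
            {"phase": "p_value", "removed": worst, "value": float(pv[worst]),
             "criterion": f"p > {p_threshold}"}
        )
        predictors.remove(worst)
        model = None

    flags: set = set()
    if not predictors:
        flags.add("all_removed")
        model = None
    return SelectionResult(model=model, retained=predictors, audit_trail=audit, flags=flags)
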