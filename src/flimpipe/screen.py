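"""Univariable weighted mixed-model screen with effect sizes.

Each feature is regressed on tissue class (cancer vs healthy) in a
weighted linear mixed model with a subject random intercept. The screen
reports, per feature, the cancer-healthy mean difference, the model's
residual SD, Cohen's d (their ratio), the Wald p-value, and the
Benjamini-Hochberg adjusted p-value across the whole screened family.
Effect magnitudes are graded at the conventional |d| cuts of 0.2 / 0.5 /
0.8 (small / medium / large).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .mixedlm import fit_weighted_lmm

__all__ = ["effect_magnitude", "univariable_screen"]


def effect_magnitude(d: float) -> str:
    a = abs(d)
    if a >= 0.8:
        return "large"
    if a >= 0.5:
        return "medium"
    if a >= 0.2:
        return "small"
    return "negligible"


def univariable_screen(
    table: pd.DataFrame,
    feature_cols: list[str],
    weights: np.ndarray,
    subject: str = "patient_id",
    label: str = "label",
) -> pd.DataFrame:
    """Run the weighted-LMM screen over a list of feature columns.

    ``table`` must carry the subject and binary tissue-label columns and be
    restricted to labeled, complete rows. Features whose model fails to
    converge are flagged and excluded from the BH family (their adjusted
    p is NaN).
    """
    labels = table[label].astype(str)
    if not set(labels.unique()) <= {"cancer", "healthy"}:
        raise ValueError("label column must be binary cancer/healthy")
    is_cancer = (labels == "cancer").to_numpy(dtype=float)
    if table.loc[labels == "cancer", subject].nunique() < 2:
        raise ValueError("need at least 2 subjects with both tissue types")
    X = pd.DataFrame({"intercept": np.ones(len(table)), "tissue_cancer": is_cancer})
    subjects = table[subject].to_numpy()

    rows = []
    for col in feature_cols:
        y = table[col].to_numpy(dtype=float)
        try:
            fit = fit_weighted_lmm(y, X, subjects, weights)
            ok = fit.converged
        except Exception:  # noqa: BLE001 - report, don't abort the screen
            fit, ok = None, False
        if fit is None:
            rows.append(
                {"feature": col, "mean_diff": np.nan, "resid_sd": np.nan,
                 "cohens_d": np.nan, "p_value": np.nan, "converged": False}
            )
            continue
        d = fit.cohens_d("tissue_cancer")
        rows.append(
            {
                "feature": col,
                "mean_diff": float(fit.params["tissue_cancer"]),
                "resid_sd": fit.sigma,
                "cohens_d": d,
                "p_value": float(fit.pvalues["tissue_cancer"]),
                "converged": ok,
            }
        )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    family = out["converged"] & out["p_value"].notna()
    if family.any():
        out.loc[family, "p_adjusted"] = multipletests(
            out.loc[family, "p_value"].to_numpy(), method="fdr_bh"
        )[1]
    out["magnitude"] = [
        effect_magnitude(d) if np.isfinite(d) else "n/a" for d in out["cohens_d"]
    ]
    return out
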