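"""Multilevel weighted principal component analysis.

High-dimensional feature blocks (the Laguerre coefficients and phasors of
each channel) are reduced to principal components computed at two levels:

* **between-subject** PCs: PCA of the weighted subject-level means, which
  capture heterogeneity across animals and are constant within an animal;
* **within-subject** PCs: PCA of the pooled weighted within-subject
  deviations (each observation minus its subject's weighted mean), which
  capture variation inside an animal.

Subjects carrying only one tissue class are excluded from fitting and
scored afterwards with the loadings estimated from the remaining
subjects. Weights enter as row masses in the covariance, which makes the
decomposition invariant to duplicating a subject's observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["MlwPcaModel", "multilevel_weighted_pca", "mlwpca_feature_blocks"]


def _weighted_pca(X: np.ndarray, row_w: np.ndarray, n_components: int):
    """PCA of rows of X with row masses row_w (normalized internally).

    Returns (loadings [p, k], variance_explained [k], mean [p]). Loadings
    are orthonormal eigenvectors of the weighted covariance, signs fixed so
    the largest-magnitude loading entry is positive.
    """
    wn = row_w / row_w.sum()
    mean = wn @ X
    Xc = X - mean
    cov = (Xc * wn[:, None]).T @ Xc
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    evecs = evecs[:, order]
    k = min(n_components, X.shape[1])
    load = evecs[:, :k]
    for j in range(k):
        i = np.argmax(np.abs(load[:, j]))
        if load[i, j] < 0:
            load[:, j] = -load[:, j]
    total = evals.sum()
    varexp = evals[:k] / total if total > 0 else np.zeros(k)
    return load, varexp, mean


@dataclass
class MlwPcaModel:
    """Fitted two-level weighted PCA for one feature block."""

    feature_cols: list[str]
    n_components: int
    between_loadings: np.ndarray  # (p, k)
    between_varexp: np.ndarray
    between_mean: np.ndarray
    within_loadings: np.ndarray  # (p, k)
    within_varexp: np.ndarray
    fit_subjects: list
    scored_subjects: list

    def transform(
        self, table: pd.DataFrame, weights: np.ndarray, subject: str = "patient_id"
    ) -> pd.DataFrame:
        """Score every observation on the between- and within-subject PCs.

        Between scores are the projected weighted subject means (constant
        within a subject); within scores are the projected deviations.
        """
        X = table[self.feature_cols].to_numpy(dtype=float)
        w = np.asarray(weights, dtype=float)
        codes, uniques = pd.factorize(table[subject].to_numpy())
        means = np.zeros((len(uniques), X.shape[1]))
        wsum = np.zeros(len(uniques))
        np.add.at(wsum, codes, w)
        np.add.at(means, codes, X * w[:, None])
        means /= wsum[:, None]
        between = (means - self.between_mean) @ self.between_loadings
        dev = X - means[codes]
        within = dev @ self.within_loadings
        out = {}
        for j in range(self.n_components):
            out[f"between_pc{j + 1}"] = between[codes, j]
            out[f"within_pc{j + 1}"] = within[:, j]
        return pd.DataFrame(out, index=table.index)


def multilevel_weighted_pca(
    table: pd.DataFrame,
    feature_cols: list[str],
    weights: np.ndarray,
    n_components: int = 2,
    subject: str = "patient_id",
    label: str = "label",
) -> MlwPcaModel:
    """Fit the two-level weighted PCA for one feature block.

    Fitting uses only subjects carrying both tissue classes (when a label
    column is present); the others are recorded as score-only subjects.
    """
    w = np.asarray(weights, dtype=float)
    subj = table[subject].to_numpy()
    all_subjects = list(pd.unique(subj))
    if label in table.columns:
        both = [
            s
            for s in all_subjects
            if table.loc[subj == s, label].nunique() == 2
        ]
    else:
        both = all_subjects
    if len(both) < max(3, n_components + 1):
        raise ValueError(
            f"need at least {max(3, n_components + 1)} two-class subjects, got {len(both)}"
        )
    fit_rows = np.isin(subj, both)
    sub = table.loc[fit_rows]
    w_fit = w[fit_rows]
    X = sub[feature_cols].to_numpy(dtype=float)
    codes, uniques = pd.factorize(sub[subject].to_numpy())
    n_s = len(uniques)
    means = np.zeros((n_s, X.shape[1]))
    wsum = np.zeros(n_s)
    np.add.at(wsum, codes, w_fit)
    np.add.at(means, codes, X * w_fit[:, None])
    means /= wsum[:, None]

    # between level: one row per subject; subject masses are their weight sums
    b_load, b_varexp, b_mean = _weighted_pca(means, wsum, n_components)
    # within level: pooled deviations with observation weights as masses
    dev = X - means[codes]
    w_load, w_varexp, _ = _weighted_pca(dev + 0.0, w_fit, n_components)
    # deviations have weighted mean zero by construction; keep the origin there

    return MlwPcaModel(
        feature_cols=list(feature_cols),
        n_components=n_components,
        between_loadings=b_load,
        between_varexp=b_varexp,
        between_mean=b_mean,
        within_loadings=w_load,
        within_varexp=w_varexp,
        fit_subjects=both,
        scored_subjects=[s for s in all_subjects if s not in both],
    )


def mlwpca_feature_blocks(columns) -> dict[str, list[str]]:
    """The per-channel Laguerre and phasor blocks reduced by MLW-PCA."""
    blocks: dict[str, list[str]] = {}
    for k in (1, 2, 3):
        lag = [c for c in columns if c.startswith("laguerre_") and c.endswith(f"_ch{k}")]
        pha = [c for c in columns if c.startswith("phasor_") and c.endswith(f"_ch{k}")]
        if lag:
            blocks[f"laguerre_ch{k}"] = lag
        if pha:
            blocks[f"phasor_ch{k}"] = pha
    return blocks
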