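"""Weighted linear mixed-effects model with a subject random intercept.

The model is

    y_i = x_i' beta + b_{s(i)} + e_i,   b_s ~ N(0, tau^2),
    e_i ~ N(0, sigma^2 / w_i),

where w_i are the analysis weights (acting as residual precisions). With a
single random intercept and a diagonal weight matrix, the marginal
covariance factorizes over subjects and every REML quantity reduces to a
handful of per-subject weighted sums via the Woodbury identity, so fitting
is exact and fast regardless of the number of observations. The variance
ratio theta = tau^2 / sigma^2 is profiled by one-dimensional REML
optimization; beta is then generalized least squares.

Cohen's d for a binary fixed effect is the estimated mean difference over
the residual SD sigma, both taken from the fitted model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = ["WeightedLMMResult", "fit_weighted_lmm"]


@dataclass
class WeightedLMMResult:
    """Fitted weighted LMM: coefficients, variances, and inference."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    sigma: float  # residual SD
    tau2: float  # random-intercept variance
    theta: float  # tau2 / sigma^2
    df_resid: int
    n_obs: int
    n_subjects: int
    reml_criterion: float
    converged: bool

    def cohens_d(self, term: str) -> float:
        """Standardized effect size: coefficient over residual SD."""
        return float(self.params[term] / self.sigma)


class _SubjectStats:
    """Per-subject weighted sufficient statistics for the Woodbury forms."""

    def __init__(self, X: np.ndarray, y: np.ndarray, w: np.ndarray, codes: np.ndarray, n_subj: int):
        p = X.shape[1]
        self.A = np.zeros((n_subj, p, p))  # X' W X
        self.a = np.zeros((n_subj, p))  # X' W 1
        self.d = np.zeros((n_subj, p))  # X' W y
        self.S = np.zeros(n_subj)  # 1' W 1
        self.u = np.zeros(n_subj)  # 1' W y
        self.yWy = np.zeros(n_subj)
        Xw = X * w[:, None]
        np.add.at(self.S, codes, w)
        np.add.at(self.u, codes, w * y)
        np.add.at(self.yWy, codes, w * y * y)
        np.add.at(self.a, codes, Xw)
        np.add.at(self.d, codes, Xw * y[:, None])
        np.add.at(self.A, codes, Xw[:, :, None] * X[:, None, :])
        self.sum_log_w = float(np.log(w).sum())

    def gls(self, theta: float):
        """X'O^-1 X, X'O^-1 y, y'O^-1 y and log|Omega| at variance ratio theta."""
        f = theta / (1.0 + theta * self.S)  # (n_subj,)
        XtOX = self.A.sum(axis=0) - np.einsum("s,si,sj->ij", f, self.a, self.a)
        XtOy = self.d.sum(axis=0) - (f * self.u) @ self.a
        ytOy = float(self.yWy.sum() - np.sum(f * self.u**2))
        logdet = float(np.log1p(theta * self.S).sum()) - self.sum_log_w
        return XtOX, XtOy, ytOy, logdet


def fit_weighted_lmm(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    subjects: np.ndarray,
    weights: np.ndarray | None = None,
) -> WeightedLMMResult:
    """Fit the weighted random-intercept LMM by REML.

    Parameters
    ----------
    y
        Outcome vector.
    X
        Fixed-effects design (include an intercept column). A DataFrame's
        column names label the coefficients.
    subjects
        Subject identifier per observation (any hashable values).
    weights
        Analysis weights (residual precisions); equal weights if omitted.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        names = [f"x{j}" for j in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    n, p = Xa.shape
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    codes, uniques = pd.factorize(np.asarray(subjects))
    n_subj = len(uniques)
    if n <= p:
        raise ValueError("more observations than fixed-effect parameters required")

    ss = _SubjectStats(Xa, y, w, codes, n_subj)

    def reml(theta: float) -> float:
        XtOX, XtOy, ytOy, logdet = ss.gls(theta)
        try:
            beta = np.linalg.solve(XtOX, XtOy)
            sign, logdet_X = np.linalg.slogdet(XtOX)
        except np.linalg.LinAlgError:
            return np.inf
        if sign <= 0:
            return np.inf
        rss = ytOy - beta @ XtOy
        if rss <= 0:
            return np.inf
        return (n - p) * np.log(rss / (n - p)) + logdet + logdet_X

    # profile the variance ratio on a log grid, then polish
    grid = np.concatenate(([0.0], np.logspace(-8, 6, 57)))
    vals = np.array([reml(t) for t in grid])
    k = int(np.nanargmin(vals))
    converged = True
    if k == 0:
        theta = 0.0
    else:
        lo = grid[max(k - 1, 1)]
        hi = grid[min(k + 1, len(grid) - 1)]
        res = optimize.minimize_scalar(
            lambda phi: reml(np.exp(phi)), bounds=(np.log(lo), np.log(hi)), method="bounded"
        )
        theta = float(np.exp(res.x))
        converged = bool(res.success)
        if reml(0.0) < res.fun:
            theta = 0.0

    XtOX, XtOy, ytOy, _ = ss.gls(theta)
    beta = np.linalg.solve(XtOX, XtOy)
    rss = ytOy - beta @ XtOy
    sigma2 = rss / (n - p)
    cov = sigma2 * np.linalg.inv(XtOX)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    pvals = 2.0 * stats.norm.sf(np.abs(z))

    return WeightedLMMResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma=float(np.sqrt(sigma2)),
        tau2=float(theta * sigma2),
        theta=float(theta),
        df_resid=n - p,
        n_obs=n,
        n_subjects=n_subj,
        reml_criterion=float(reml(theta)),
        converged=converged,
    )
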