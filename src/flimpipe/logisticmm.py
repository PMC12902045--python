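"""Weighted logistic mixed-effects model (random intercept, Laplace fit).

Binary tissue class (cancer = 1) is modeled as

    logit P(y_i = 1 | b) = x_i' beta + b_{s(i)},   b_s ~ N(0, tau^2),

with analysis weights w_i entering the log-likelihood multiplicatively.
For a fixed random-intercept variance tau^2, (beta, b) are found by damped
Newton iterations on the penalized weighted log-likelihood; the marginal
likelihood is then approximated by the Laplace method, whose correction
term is diagonal because the random effect is a scalar intercept per
subject. tau^2 is profiled by one-dimensional optimization of that
Laplace objective. Standard errors come from the fixed-effects block of
the inverse joint Hessian (Schur complement), matching the convention
that a positive coefficient means higher predictor values raise the
probability of cancer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import expit

__all__ = ["LogisticMMResult", "fit_weighted_logistic_mixed"]

_MAX_ABS_ETA = 30.0


@dataclass
class LogisticMMResult:
    """Fitted weighted logistic mixed model."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    tau2: float
    random_effects: pd.Series
    loglik_laplace: float
    n_obs: int
    n_subjects: int
    converged: bool
    flags: set = field(default_factory=set)

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coefficient": self.params, "se": self.bse, "p_value": self.pvalues}
        )


def _penalized_mode(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    codes: np.ndarray,
    n_subj: int,
    tau2: float,
    beta0: np.ndarray,
    b0: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
) -> tuple[np.ndarray, np.ndarray, float, np.ndarray, bool]:
    """Damped Newton ascent of the penalized weighted log-likelihood.

    Returns (beta, b, penalized loglik, per-subject curvature d_s, converged).
    """
    n, p = X.shape
    beta, b = beta0.copy(), b0.copy()

    def pen_ll(beta: np.ndarray, b: np.ndarray) -> float:
        eta = np.clip(X @ beta + b[codes], -_MAX_ABS_ETA, _MAX_ABS_ETA)
        ll = float(np.sum(w * (y * eta - np.logaddexp(0.0, eta))))
        return ll - float(np.sum(b**2) / (2.0 * tau2))

    current = pen_ll(beta, b)
    converged = False
    d_s = np.full(n_subj, np.nan)
    for _ in range(max_iter):
        eta = np.clip(X @ beta + b[codes], -_MAX_ABS_ETA, _MAX_ABS_ETA)
        mu = expit(eta)
        v = w * mu * (1.0 - mu)
        g_beta = X.T @ (w * (y - mu))
        g_b = np.zeros(n_subj)
        np.add.at(g_b, codes, w * (y - mu))
        g_b -= b / tau2
        d_s = np.zeros(n_subj)
        np.add.at(d_s, codes, v)
        H_bb = d_s + 1.0 / tau2
        Xv = X * v[:, None]
        H_bx = np.zeros((n_subj, p))
        np.add.at(H_bx, codes, Xv)
        H_xx = X.T @ Xv
        # Schur complement on the diagonal b-block
        S = H_xx - H_bx.T @ (H_bx / H_bb[:, None])
        rhs = g_beta - H_bx.T @ (g_b / H_bb)
        try:
            d_beta = np.linalg.solve(S, rhs)
        except np.linalg.LinAlgError:
            d_beta = np.linalg.lstsq(S, rhs, rcond=None)[0]
        d_b = (g_b - H_bx @ d_beta) / H_bb
        step = 1.0
        for _half in range(30):
            cand = pen_ll(beta + step * d_beta, b + step * d_b)
            if cand >= current - 1e-12:
                break
            step *= 0.5
        beta = beta + step * d_beta
        b = b + step * d_b
        if abs(cand - current) < tol * (1.0 + abs(current)):
            current = cand
            converged = True
            break
        current = cand
    return beta, b, current, d_s, converged


def fit_weighted_logistic_mixed(
    y: np.ndarray,
    X: pd.DataFrame | np.ndarray,
    subjects: np.ndarray,
    weights: np.ndarray | None = None,
    tau2_bounds: tuple[float, float] = (1e-8, 1e3),
) -> LogisticMMResult:
    """Fit the weighted logistic random-intercept model by Laplace ML.

    ``y`` is binary (1 = cancer); ``X`` should include an intercept column.
    Complete separation is detected heuristically (runaway coefficients)
    and flagged rather than raised, with the coefficients reported as-is.
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
    codes, uniques = pd.factorize(np.asarray(subjects))
    n_subj = len(uniques)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")

    state = {"beta": np.zeros(p), "b": np.zeros(n_subj)}

    def laplace_objective(log_tau2: float) -> float:
        tau2 = float(np.exp(log_tau2))
        beta, b, pll, d_s, _ = _penalized_mode(
            Xa, y, w, codes, n_subj, tau2, state["beta"], state["b"]
        )
        state["beta"], state["b"] = beta, b
        return -(pll - 0.5 * float(np.log1p(tau2 * d_s).sum()))

    res = optimize.minimize_scalar(
        laplace_objective,
        bounds=(np.log(tau2_bounds[0]), np.log(tau2_bounds[1])),
        method="bounded",
        options={"xatol": 1e-4},
    )
    tau2 = float(np.exp(res.x))
    beta, b, pll, d_s, inner_ok = _penalized_mode(
        Xa, y, w, codes, n_subj, tau2, state["beta"], state["b"]
    )
    loglik = pll - 0.5 * float(np.log1p(tau2 * d_s).sum())

    # joint Hessian at the mode -> fixed-effect covariance via Schur complement
    eta = np.clip(Xa @ beta + b[codes], -_MAX_ABS_ETA, _MAX_ABS_ETA)
    mu = expit(eta)
    v = w * mu * (1.0 - mu)
    Xv = Xa * v[:, None]
    H_bb = np.zeros(n_subj)
    np.add.at(H_bb, codes, v)
    H_bb += 1.0 / tau2
    H_bx = np.zeros((n_subj, p))
    np.add.at(H_bx, codes, Xv)
    S = Xa.T @ Xv - H_bx.T @ (H_bx / H_bb[:, None])
    try:
        cov = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(S)
    se = np.sqrt(np.clip(np.diag(cov), 0.0, None))

    flags: set = set()
    if np.any(np.abs(beta) > 15.0) or np.any(se > 1e3):
        flags.add("separation_suspected")

    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.norm.sf(np.abs(z))
    return LogisticMMResult(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        pvalues=pd.Series(pvals, index=names),
        tau2=tau2,
        random_effects=pd.Series(b, index=list(uniques)),
        loglik_laplace=float(loglik),
        n_obs=n,
        n_subjects=n_subj,
        converged=bool(res.success and inner_ok),
        flags=flags,
    )
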