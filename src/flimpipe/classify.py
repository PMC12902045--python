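"""Per-patient cancer/healthy classification with feature-combination search.

Evaluation follows a leave-one-patient-out (LOPO) protocol: for each
patient carrying both tissue classes, a classifier is trained on all other
patients' points (using the analysis weights so each patient and tissue
contributes equally) and scored on the held-out patient, yielding a
per-patient ROC/AUC plus accuracy, sensitivity and specificity at the 0.5
probability threshold. A grid search over all 15 non-empty combinations
of the four feature groups (lifetimes, intensity ratios, Laguerre
coefficients, phasors) ranks combos by mean per-patient AUC under
identical seeds. Model families are a decision tree (default) and linear
discriminant analysis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.tree import DecisionTreeClassifier

from .features import FEATURE_GROUPS, feature_columns

__all__ = [
    "FeatureCombo",
    "enumerate_combos",
    "make_classifier",
    "evaluate_patient",
    "grid_search_combos",
    "optimize_hyperparameters",
    "summarize_cohort",
]


@dataclass(frozen=True)
class FeatureCombo:
    """A non-empty subset of the four feature groups."""

    groups: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("combo must be non-empty")
        unknown = set(self.groups) - set(FEATURE_GROUPS)
        if unknown:
            raise ValueError(f"unknown feature groups: {sorted(unknown)}")

    @property
    def name(self) -> str:
        return "+".join(self.groups)

    def resolve(self, columns) -> list[str]:
        return feature_columns(columns, self.groups)


def enumerate_combos() -> list[FeatureCombo]:
    """All 15 non-empty feature-group subsets, in deterministic order."""
    combos = []
    for r in range(1, len(FEATURE_GROUPS) + 1):
        for sub in itertools.combinations(FEATURE_GROUPS, r):
            combos.append(FeatureCombo(groups=sub))
    return combos


def make_classifier(family: str, hyperparameters: dict | None = None, seed: int = 0):
    hp = dict(hyperparameters or {})
    if family == "tree":
        hp.setdefault("max_depth", 6)
        hp.setdefault("min_samples_leaf", 20)
        return DecisionTreeClassifier(random_state=seed, **hp)
    if family == "lda":
        return LinearDiscriminantAnalysis(**hp)
    raise ValueError(f"unknown model family {family!r} (expected 'tree' or 'lda')")


def _metrics_at_half(y: np.ndarray, prob: np.ndarray) -> dict:
    pred = prob >= 0.5
    tp = int(np.sum(pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return {
        "accuracy": (tp + tn) / len(y),
        "sensitivity": tp / (tp + fn) if (tp + fn) else np.nan,
        "specificity": tn / (tn + fp) if (tn + fp) else np.nan,
    }


def evaluate_patient(
    table: pd.DataFrame,
    columns: list[str],
    test_patient: str,
    family: str = "tree",
    hyperparameters: dict | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    subject: str = "patient_id",
    label: str = "label",
) -> dict:
    """LOPO evaluation of one held-out patient.

    Trains on every other patient's points (sample-weighted) and scores the
    held-out patient's points. Returns AUC, threshold-0.5 metrics, and the
    ROC curve; a single-class test patient is reported as excluded (AUC is
    undefined there).
    """
    y_all = (table[label].astype(str) == "cancer").to_numpy(dtype=int)
    test_rows = (table[subject] == test_patient).to_numpy()
    y_test = y_all[test_rows]
    if len(np.unique(y_test)) < 2:
        return {"patient_id": test_patient, "excluded": True, "reason": "single_class"}
    clf = make_classifier(family, hyperparameters, seed)
    fit_kwargs = {}
    if weights is not None:
        from sklearn.utils.validation import has_fit_parameter

        if has_fit_parameter(clf, "sample_weight"):
            fit_kwargs["sample_weight"] = np.asarray(weights, dtype=float)[~test_rows]
    clf.fit(table.loc[~test_rows, columns].to_numpy(), y_all[~test_rows], **fit_kwargs)
    prob = clf.predict_proba(table.loc[test_rows, columns].to_numpy())[:, 1]
    fpr, tpr, _thr = roc_curve(y_test, prob)
    out = {
        "patient_id": test_patient,
        "excluded": False,
        "auc": float(roc_auc_score(y_test, prob)),
        "n_points": int(test_rows.sum()),
        "roc_fpr": fpr,
        "roc_tpr": tpr,
    }
    out.update(_metrics_at_half(y_test, prob))
    return out


def _eligible_patients(table: pd.DataFrame, subject: str, label: str) -> list[str]:
    out = []
    for pid, g in table.groupby(subject, observed=True):
        if g[label].astype(str).nunique() == 2:
            out.append(pid)
    return out


def lopo_mean_auc(
    table: pd.DataFrame,
    columns: list[str],
    family: str,
    hyperparameters: dict | None,
    weights: np.ndarray | None,
    seed: int,
    subject: str = "patient_id",
    label: str = "label",
) -> tuple[float, pd.DataFrame]:
    """Mean per-patient LOPO AUC over all two-class patients."""
    reports = []
    for pid in _eligible_patients(table, subject, label):
        rep = evaluate_patient(
            table, columns, pid, family, hyperparameters, weights, seed, subject, label
        )
        if not rep.get("excluded"):
            reports.append({k: v for k, v in rep.items() if not k.startswith("roc_")})
    frame = pd.DataFrame(reports)
    return float(frame["auc"].mean()) if len(frame) else np.nan, frame


def grid_search_combos(
    table: pd.DataFrame,
    family: str = "tree",
    hyperparameters: dict | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    subject: str = "patient_id",
    label: str = "label",
) -> pd.DataFrame:
    """Evaluate all 15 feature-group combos under one LOPO protocol.

    Returns the ranking (descending mean per-patient AUC; ties broken by
    combo order, so ranking is deterministic given the seed).
    """
    rows = []
    for combo in enumerate_combos():
        cols = combo.resolve(table.columns)
        if not cols:
            continue
        mean_auc, frame = lopo_mean_auc(
            table, cols, family, hyperparameters, weights, seed, subject, label
        )
        rows.append(
            {
                "combo": combo.name,
                "n_groups": len(combo.groups),
                "n_features": len(cols),
                "mean_auc": mean_auc,
                "sd_auc": float(frame["auc"].std(ddof=1)) if len(frame) > 1 else 0.0,
                "n_patients": len(frame),
            }
        )
    out = pd.DataFrame(rows)
    return out.sort_values("mean_auc", ascending=False, kind="stable").reset_index(drop=True)


def optimize_hyperparameters(
    table: pd.DataFrame,
    columns: list[str],
    search_space: dict[str, list],
    family: str = "tree",
    budget: int = 25,
    weights: np.ndarray | None = None,
    seed: int = 0,
    subject: str = "patient_id",
    label: str = "label",
) -> tuple[dict, pd.DataFrame]:
    """Sequential hyperparameter search maximizing LOPO mean AUC.

    The finite search space is enumerated in deterministic order; when it
    fits within the budget the search is exhaustive, otherwise a seeded
    random subset of ``budget`` configurations is evaluated. Every trial is
    logged. Returns ``(best hyperparameters, trial log)``.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    keys = sorted(search_space)
    grid = [dict(zip(keys, values)) for values in itertools.product(*(search_space[k] for k in keys))]
    if len(grid) > budget:
        rng = np.random.default_rng(seed)
        grid = [grid[i] for i in rng.choice(len(grid), size=budget, replace=False)]
    log = []
    for trial, hp in enumerate(grid):
        score, _ = lopo_mean_auc(table, columns, family, hp, weights, seed, subject, label)
        log.append({"trial": trial, **hp, "mean_auc": score})
    frame = pd.DataFrame(log)
    best = grid[int(frame["mean_auc"].idxmax())]
    return best, frame


def summarize_cohort(per_patient: pd.DataFrame, exclude: list[str] | None = None) -> dict:
    """Cohort rollup of per-patient metrics: mean, SD, median.

    ``exclude`` drops named patients from the rollup (e.g. a known
    outlier); a single-patient rollup reports SD 0 with a flag.
    """
    frame = per_patient
    if exclude:
        frame = frame[~frame["patient_id"].isin(exclude)]
    metrics = [m for m in ("auc", "accuracy", "sensitivity", "specificity") if m in frame]
    out: dict = {"n_patients": int(len(frame)), "flags": []}
    for m in metrics:
        vals = frame[m].to_numpy(dtype=float)
        out[f"{m}_mean"] = float(np.nanmean(vals))
        out[f"{m}_median"] = float(np.nanmedian(vals))
        if len(vals) > 1:
            out[f"{m}_sd"] = float(np.nanstd(vals, ddof=1))
        else:
            out[f"{m}_sd"] = 0.0
            if "single_patient_sd_undefined" not in out["flags"]:
                out["flags"].append("single_patient_sd_undefined")
    return out
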