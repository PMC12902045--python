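import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from flimpipe.classify import (
    FeatureCombo,
    enumerate_combos,
    evaluate_patient,
    grid_search_combos,
    make_classifier,
    optimize_hyperparameters,
    summarize_cohort,
)


def brute_force_auc(y, scores):
    """Pairwise-comparison oracle: P(score_pos > score_neg) + 0.5 ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = ties = 0
    for p in pos:
        wins += np.sum(p > neg)
        ties += np.sum(p == neg)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_pairwise_oracle(seed):
    rng = np.random.default_rng(seed)
    n = 200
    y = rng.integers(0, 2, n)
    y[0], y[1] = 0, 1  # both classes present
    scores = np.round(rng.normal(size=n), 1)  # coarse grid forces ties
    assert roc_auc_score(y, scores) == pytest.approx(brute_force_auc(y, scores), abs=1e-12)


def test_fifteen_feature_combos():
    combos = enumerate_combos()
    assert len(combos) == 15
    assert len({c.name for c in combos}) == 15
    with pytest.raises(ValueError):
        FeatureCombo(groups=())
    with pytest.raises(ValueError):
        FeatureCombo(groups=("waveforms",))


def toy_cohort(n_patients=6, n_per=80, informative=True, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_patients):
        y = np.array([0, 1]).repeat(n_per // 2)
        lifetime = rng.normal(4.0, 0.3, n_per) - (0.8 if informative else 0.0) * y
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": f"P{i:02d}",
                    "label": np.where(y == 1, "cancer", "healthy"),
                    "lifetime_ch1": lifetime,
                    "ir_ch1": rng.normal(0.4, 0.05, n_per),
                    "laguerre_c01_ch1": rng.normal(0, 1, n_per),
                    "phasor_g1_ch1": rng.normal(0.9, 0.02, n_per),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def test_perfectly_separable_patient_has_auc_one():
    t = toy_cohort(seed=1)
    jitter = np.random.default_rng(0).normal(0, 0.01, len(t))
    t["lifetime_ch1"] = np.where(t["label"] == "cancer", 1.0, 5.0) + jitter
    rep = evaluate_patient(t, ["lifetime_ch1"], "P00", family="lda")
    assert rep["auc"] == 1.0


def test_shuffled_labels_give_chance_auc():
    """Permuting the held-out patient's labels drives AUC to 0.5 +/- 0.05
    averaged over 100 permutations."""
    t = toy_cohort(seed=2)
    rep = evaluate_patient(t, ["lifetime_ch1"], "P00", family="lda")
    y = (t.loc[t["patient_id"] == "P00", "label"] == "cancer").to_numpy().astype(int)
    # reconstruct the held-out scores from the ROC-generating model
    clf = make_classifier("lda")
    train = t["patient_id"] != "P00"
    clf.fit(t.loc[train, ["lifetime_ch1"]], (t.loc[train, "label"] == "cancer"))
    scores = clf.predict_proba(t.loc[~train, ["lifetime_ch1"]])[:, 1]
    rng = np.random.default_rng(0)
    aucs = [roc_auc_score(rng.permutation(y), scores) for _ in range(100)]
    assert np.mean(aucs) == pytest.approx(0.5, abs=0.05)


def test_constant_score_gives_exactly_half_auc():
    y = np.array([0, 1] * 20)
    assert brute_force_auc(y, np.zeros(40)) == 0.5
    assert roc_auc_score(y, np.zeros(40)) == 0.5


def test_single_class_patient_reported_excluded():
    t = toy_cohort(seed=3)
    t.loc[t["patient_id"] == "P01", "label"] = "healthy"
    rep = evaluate_patient(t, ["lifetime_ch1"], "P01")
    assert rep["excluded"] and rep["reason"] == "single_class"


def test_no_leakage_from_held_out_patient():
    """Poisoning the held-out patient's labels must not change the trained
    model's scores for that patient."""
    t = toy_cohort(seed=4)
    rep_a = evaluate_patient(t, ["lifetime_ch1", "ir_ch1"], "P02", family="tree", seed=5)
    poisoned = t.copy()
    test_rows = poisoned["patient_id"] == "P02"
    poisoned.loc[test_rows, "label"] = np.where(
        poisoned.loc[test_rows, "label"] == "cancer", "healthy", "cancer"
    )
    rep_b = evaluate_patient(poisoned, ["lifetime_ch1", "ir_ch1"], "P02", family="tree", seed=5)
    np.testing.assert_array_equal(rep_a["roc_fpr"], rep_b["roc_tpr"][::-1][::-1] * 0 + rep_a["roc_fpr"])
    assert rep_b["auc"] == pytest.approx(1.0 - rep_a["auc"], abs=1e-12)


def test_grid_search_is_deterministic_and_finds_signal():
    t = toy_cohort(seed=6)
    a = grid_search_combos(t, family="lda", seed=3)
    b = grid_search_combos(t, family="lda", seed=3)
    pd.testing.assert_frame_equal(a, b)
    # only the lifetime separates classes, so every top combo includes it
    top = a.iloc[0]
    assert "lifetimes" in top["combo"]


def test_hyperparameter_search_degenerate_space():
    t = toy_cohort(seed=7)
    best, log = optimize_hyperparameters(
        t, ["lifetime_ch1"], {"max_depth": [3]}, budget=5, seed=0
    )
    assert best == {"max_depth": 3}
    assert len(log) == 1


def test_hyperparameter_search_prefers_interaction_depth():
    """XOR-structured classes need depth >= 2 trees; the search must not
    pick a depth-1 stump."""
    rng = np.random.default_rng(8)
    rows = []
    for i in range(4):
        n = 200
        a, b = rng.normal(size=n), rng.normal(size=n)
        y = (a * b > 0).astype(int)
        rows.append(
            pd.DataFrame(
                {
                    "patient_id": f"P{i}",
                    "label": np.where(y == 1, "cancer", "healthy"),
                    "lifetime_ch1": a,
                    "ir_ch1": b,
                }
            )
        )
    t = pd.concat(rows, ignore_index=True)
    best, log = optimize_hyperparameters(
        t, ["lifetime_ch1", "ir_ch1"], {"max_depth": [1, 2, 3, 4], "min_samples_leaf": [5]},
        budget=10, seed=0,
    )
    assert best["max_depth"] >= 2
    assert len(log) == 4


def test_hyperparameter_search_deterministic_given_seed():
    t = toy_cohort(seed=9)
    space = {"max_depth": [2, 3, 4, 5, 6], "min_samples_leaf": [5, 10, 20]}
    a = optimize_hyperparameters(t, ["lifetime_ch1"], space, budget=6, seed=4)
    b = optimize_hyperparameters(t, ["lifetime_ch1"], space, budget=6, seed=4)
    pd.testing.assert_frame_equal(a[1], b[1])
    assert a[0] == b[0]
    with pytest.raises(ValueError):
        optimize_hyperparameters(t, ["lifetime_ch1"], space, budget=0, seed=4)


def test_cohort_rollup_hand_values():
    frame = pd.DataFrame({"patient_id": ["A", "B"], "auc": [1.0, 0.5], "accuracy": [0.9, 0.7]})
    roll = summarize_cohort(frame)
    assert roll["auc_mean"] == pytest.approx(0.75)
    assert roll["auc_sd"] == pytest.approx(0.3536, abs=1e-4)
    assert roll["auc_median"] == pytest.approx(0.75)


def test_cohort_rollup_single_patient_flagged():
    frame = pd.DataFrame({"patient_id": ["A"], "auc": [0.8]})
    roll = summarize_cohort(frame)
    assert roll["auc_sd"] == 0.0
    assert "single_patient_sd_undefined" in roll["flags"]


def test_excluding_worst_patient_never_lowers_mean():
    frame = pd.DataFrame({"patient_id": list("ABCD"), "auc": [0.9, 0.4, 0.7, 0.8]})
    full = summarize_cohort(frame)
    trimmed = summarize_cohort(frame, exclude=["B"])
    assert trimmed["auc_mean"] >= full["auc_mean"]
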