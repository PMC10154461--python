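import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import auc_pair_count, net_benefit_confusion, pauc_dense_grid
from rimshrink.errors import ConfigError, DataError, InsufficientDataError
from rimshrink.evaluation import (
    auc_mannwhitney,
    compare_scores,
    decision_curve,
    mcnemar_test,
    operating_point,
    pauc_high_spec,
    roc_auc,
    roc_points,
    run_report,
)


# ---------------------------------------------------------------------------
# AUC

def test_auc_perfect_separation_and_hand_example():
    assert auc_mannwhitney([1, 2, 3, 10, 11, 12], [0, 0, 0, 1, 1, 1]) == 1.0
    assert auc_mannwhitney([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)
    assert auc_mannwhitney([0.5] * 6, [0, 0, 0, 1, 1, 1]) == pytest.approx(0.5)


@pytest.mark.parametrize("seed", range(5))
def test_auc_matches_pair_count_oracle_with_ties(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=40), 1)  # rounding induces ties
    labels = rng.random(40) > 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    assert auc_mannwhitney(scores, labels) == pytest.approx(
        auc_pair_count(scores, labels), abs=1e-12)


def test_delong_ci_contains_point_estimate(rng):
    scores = rng.normal(size=60) + np.r_[np.ones(30), np.zeros(30)]
    labels = np.r_[np.ones(30), np.zeros(30)].astype(bool)
    out = roc_auc(scores, labels)
    assert out["ci_low"] <= out["auc"] <= out["ci_high"]
    assert 0.0 <= out["ci_low"] and out["ci_high"] <= 1.0
    with pytest.raises(DataError):
        roc_auc([1, 2, 3], [1, 1, 1])


# ---------------------------------------------------------------------------
# pAUC

def test_pauc_perfect_classifier_is_0_05():
    scores = [1, 2, 3, 10, 11, 12]
    labels = [0, 0, 0, 1, 1, 1]
    out = pauc_high_spec(scores, labels, n_boot=10, seed=0)
    assert out["pauc"] == pytest.approx(0.05, abs=1e-12)


def test_pauc_all_tied_scores_is_triangle_area():
    out = pauc_high_spec([0.5] * 10, [0, 1] * 5, n_boot=10, seed=0)
    assert out["pauc"] == pytest.approx(0.00125, abs=1e-12)


@pytest.mark.parametrize("seed", range(4))
def test_pauc_matches_dense_grid_oracle(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=60) + np.r_[np.full(30, 0.8), np.zeros(30)]
    labels = np.r_[np.ones(30), np.zeros(30)].astype(bool)
    out = pauc_high_spec(scores, labels, n_boot=10, seed=0)
    assert out["pauc"] == pytest.approx(pauc_dense_grid(scores, labels), abs=1e-9)


def test_pauc_bootstrap_ci_is_seeded_and_contains_estimate(rng):
    scores = rng.normal(size=50) + np.r_[np.ones(25), np.zeros(25)]
    labels = np.r_[np.ones(25), np.zeros(25)].astype(bool)
    a = pauc_high_spec(scores, labels, n_boot=200, seed=9)
    b = pauc_high_spec(scores, labels, n_boot=200, seed=9)
    assert a == b
    assert a["ci_low"] <= a["pauc"] + 1e-12
    assert 0.0 <= a["pauc"] <= 0.05


def test_full_range_integration_reproduces_auc(rng):
    scores = np.round(rng.normal(size=50), 1)
    labels = rng.random(50) > 0.4
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    fpr, tpr = roc_points(scores, labels)
    full = np.trapezoid(tpr, fpr)
    assert full == pytest.approx(auc_mannwhitney(scores, labels), abs=1e-12)


# ---------------------------------------------------------------------------
# operating points

def test_operating_points_perfect_scores():
    scores = [1, 2, 3, 10, 11, 12]
    labels = [0, 0, 0, 1, 1, 1]
    for policy in ("youden", "spec95"):
        op = operating_point(scores, labels, policy)
        assert op["sensitivity"] == 1.0
        assert op["specificity"] == 1.0
        assert op["accuracy"] == 1.0


def test_spec95_smallest_threshold_hand_example():
    op = operating_point([1, 2, 3, 4, 5], [0, 0, 0, 1, 1], "spec95")
    assert op["threshold"] == 4.0
    assert op["sensitivity"] == 1.0
    assert op["specificity"] == 1.0


def _scan_youden(scores, labels):
    scores = np.asarray(scores, float)
    y = np.asarray(labels, bool)
    uniq = np.unique(scores)
    best = None
    for thr in np.r_[uniq, uniq[-1] + 1]:
        pred = scores >= thr
        sens = (pred & y).sum() / y.sum()
        spec = (~pred & ~y).sum() / (~y).sum()
        key = (sens + spec - 1, spec, thr)
        if best is None or key > best[0]:
            best = (key, thr, sens, spec)
    return best


@pytest.mark.parametrize("seed", range(5))
def test_youden_tie_break_matches_exhaustive_scan(seed):
    rng = np.random.default_rng(seed)
    scores = np.round(rng.normal(size=30), 1)
    labels = rng.random(30) > 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    op = operating_point(scores, labels, "youden")
    _, thr, sens, spec = _scan_youden(scores, labels)
    assert op["threshold"] == pytest.approx(thr)
    assert op["sensitivity"] == pytest.approx(sens)
    assert op["specificity"] == pytest.approx(spec)


def test_unknown_policy_is_config_error():
    with pytest.raises(ConfigError):
        operating_point([1, 2], [0, 1], "magic")


# ---------------------------------------------------------------------------
# McNemar

def test_mcnemar_identical_predictions_p_one():
    labels = np.array([1, 1, 0, 0, 1], bool)
    pred = np.array([1, 0, 0, 1, 1], bool)
    assert mcnemar_test(pred, pred, labels) == 1.0


def test_mcnemar_exact_binomial_closed_form():
    # a correct on 10 cases where b is wrong, none the other way:
    # exact two-sided P = 2 * 0.5^10
    labels = np.ones(12, bool)
    pred_a = np.ones(12, bool)
    pred_b = np.r_[np.zeros(10), np.ones(2)].astype(bool)
    assert mcnemar_test(pred_a, pred_b, labels) == pytest.approx(2 * 0.5**10, rel=1e-9)


def test_mcnemar_symmetric_discordance_p_one():
    labels = np.ones(14, bool)
    pred_a = np.r_[np.zeros(7), np.ones(7)].astype(bool)
    pred_b = np.r_[np.ones(7), np.zeros(7)].astype(bool)
    assert mcnemar_test(pred_a, pred_b, labels) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# pairwise score comparison

def test_compare_scores_identical_methods_adjusted_one(rng):
    scores = rng.normal(size=30)
    labels = np.r_[np.ones(15), np.zeros(15)].astype(bool)
    df = compare_scores({"A": scores, "B": scores.copy()}, labels)
    assert (df["p_adjusted"] == 1.0).all()


def test_bonferroni_multiplier_is_six_for_four_methods(rng):
    labels = np.r_[np.ones(20), np.zeros(20)].astype(bool)
    sets = {m: rng.normal(size=40) for m in "ABCD"}
    df = compare_scores(sets, labels)
    assert len(df) == 12  # 6 pairs x 2 classes
    np.testing.assert_allclose(df["p_adjusted"],
                               np.minimum(1.0, 6 * df["p_raw"]))


def test_compare_scores_matches_scipy_exact_enumeration(rng):
    labels = np.r_[np.ones(8), np.zeros(8)].astype(bool)
    a = rng.normal(size=16)
    b = a + rng.normal(scale=0.5, size=16)
    df = compare_scores({"A": a, "B": b}, labels)
    row = df[(df["class"] == "positive")].iloc[0]
    expected = stats.wilcoxon(a[labels], b[labels], alternative="two-sided",
                              zero_method="wilcox", method="exact").pvalue
    assert row["p_raw"] == pytest.approx(expected, abs=1e-12)


def test_compare_scores_insufficient_pairs(rng):
    labels = np.r_[np.ones(3), np.zeros(10)].astype(bool)
    with pytest.raises(InsufficientDataError):
        compare_scores({"A": rng.normal(size=13), "B": rng.normal(size=13)}, labels)


# ---------------------------------------------------------------------------
# decision curves

def test_decision_curve_closed_forms():
    # perfect probabilities at prevalence 0.5: NB = 0.5 at every threshold
    prob = np.r_[np.ones(10), np.zeros(10)]
    labels = np.r_[np.ones(10), np.zeros(10)].astype(bool)
    df = decision_curve(prob, labels)
    np.testing.assert_allclose(df["net_benefit_model"], 0.5)
    row = df[np.isclose(df["threshold"], 0.2)].iloc[0]
    assert row["net_benefit_all"] == pytest.approx(0.5 - 0.5 * 0.25)
    assert (df["net_benefit_none"] == 0.0).all()
    # net benefit never exceeds prevalence
    assert (df["net_benefit_model"] <= 0.5 + 1e-12).all()


def test_decision_curve_matches_confusion_matrix_oracle(rng):
    prob = rng.random(50)
    labels = rng.random(50) > 0.6
    df = decision_curve(prob, labels)
    for _, row in df.iloc[::7].iterrows():
        expected = net_benefit_confusion(prob, labels, row["threshold"])
        assert row["net_benefit_model"] == pytest.approx(expected, abs=1e-12)


def test_decision_curve_rejects_bad_inputs(rng):
    with pytest.raises(DataError):
        decision_curve([0.5, 1.2], [0, 1])
    with pytest.raises(ConfigError):
        decision_curve([0.5, 0.6], [0, 1], thresholds=[0.5, 1.0])


# ---------------------------------------------------------------------------
# report

def test_run_report_structure_and_recomputability(rng):
    payload = {}
    for m in ("MAX", "MAX_E", "ALL", "ALL_E"):
        for split in ("train", "validation"):
            n = 40 if split == "train" else 10
            labels = ["adenoma"] * (n // 2) + ["non_adenoma"] * (n // 2)
            scores = rng.normal(size=n) + np.r_[np.ones(n // 2), np.zeros(n // 2)]
            payload[(m, split)] = (scores, labels)
    report = run_report(payload, pauc_seed=0, n_boot=20)
    assert len(report.roc) == 8
    table = report.table("validation")
    assert set(table.index) == {"MAX", "MAX_E", "ALL", "ALL_E"}
    for col in ("AUC", "SEN", "SPE", "ACC", "pAUC", "SEN_spec95"):
        assert col in table.columns
    assert len(report.mcnemar_sens) == 6
    assert ((report.score_comparisons["p_adjusted"] > 0)
            & (report.score_comparisons["p_adjusted"] <= 1)).all()
    assert set(report.dca) == {"MAX", "MAX_E", "ALL", "ALL_E"}
    # every reported AUC is recomputable from the serialized scores
    for (m, s), r in report.roc.items():
        sc, lb = report.scores[(m, s)]
        assert r.auc == pytest.approx(auc_mannwhitney(sc, lb))
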