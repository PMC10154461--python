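import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oracles import icc_2_1_mean_squares
from rimshrink.errors import AlignmentError, InsufficientDataError
from rimshrink.selection import (
    RadiomicsModel,
    fit_model,
    icc_2_1,
    lasso_1se,
    rfe_select,
    run_cascade,
    split_train_val,
    stability_filter,
    univariate_filter,
)


# ---------------------------------------------------------------------------
# ICC

def test_icc_perfect_agreement_is_one():
    assert icc_2_1([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)


def test_icc_constant_shift_penalized_below_one():
    v = [1.0, 2.0, 3.0, 4.0, 5.0]
    shifted = [x + 2.0 for x in v]
    assert icc_2_1(v, shifted) < 1.0


def test_icc_matches_mean_squares_oracle_small_table():
    y1 = [9.0, 6.0, 8.0, 7.0, 10.0, 6.0]
    y2 = [2.0, 1.0, 4.0, 1.0, 5.0, 2.0]
    assert icc_2_1(y1, y2) == pytest.approx(icc_2_1_mean_squares(y1, y2), abs=1e-9)


@pytest.mark.parametrize("seed", range(10))
def test_icc_matches_oracles_on_random_tables(seed):
    rng = np.random.default_rng(seed)
    y1 = rng.normal(size=20)
    y2 = 0.8 * y1 + rng.normal(scale=0.5, size=20) + 0.3
    got = icc_2_1(y1, y2)
    assert got == pytest.approx(icc_2_1_mean_squares(y1, y2), abs=1e-9)


def test_icc_against_pingouin():
    pg = pytest.importorskip("pingouin")
    rng = np.random.default_rng(42)
    y1 = rng.normal(size=15)
    y2 = y1 + rng.normal(scale=0.4, size=15)
    df = pd.DataFrame({
        "subject": list(range(15)) * 2,
        "rater": ["a"] * 15 + ["b"] * 15,
        "score": np.r_[y1, y2],
    })
    ref = pg.intraclass_corr(df, targets="subject", raters="rater", ratings="score")
    sel = ref[ref["Type"].isin(["ICC2", "ICC(A,1)"])]  # absolute agreement, single rater
    icc2 = float(sel["ICC"].iloc[0])
    assert icc_2_1(y1, y2) == pytest.approx(icc2, abs=1e-9)


def test_stability_filter_identity_noise_and_threshold(rng):
    names = [f"f{i}" for i in range(10)]
    idx = [f"c{i}" for i in range(20)]
    t1 = pd.DataFrame(rng.normal(size=(20, 10)), index=idx, columns=names)
    report = stability_filter(t1, t1.copy())
    assert report.retained == names

    t2 = t1.copy()
    t2["f3"] = rng.normal(size=20)  # independent noise for one feature
    report = stability_filter(t1, t2)
    assert "f3" in report.excluded
    assert len(report.excluded) <= 2

    report = stability_filter(t1, t1 + rng.normal(scale=1e-6, size=(20, 10)),
                              threshold=1.0)
    assert report.retained == []  # any noise at threshold 1.0 excludes all

    with pytest.raises(AlignmentError):
        stability_filter(t1, t1.set_axis([f"x{i}" for i in range(20)], axis=0))


# ---------------------------------------------------------------------------
# univariate

def test_univariate_keeps_separated_drops_identical(rng):
    n = 50
    labels = ["adenoma"] * n + ["non_adenoma"] * n
    table = pd.DataFrame({
        "good": np.r_[rng.normal(3, 1, n), rng.normal(0, 1, n)],
        "same": np.r_[np.ones(n), np.ones(n)],
        "noise": rng.normal(size=2 * n),
    })
    survivors, pvals = univariate_filter(table, labels)
    assert "good" in survivors
    assert "same" not in survivors
    assert pvals["same"] == 1.0


def test_univariate_small_sample_matches_exact_u_distribution():
    a = [1.2, 3.4, 0.5, 2.2]
    b = [4.1, 5.0, 3.9, 6.2]
    table = pd.DataFrame({"f": a + b})
    labels = ["adenoma"] * 4 + ["non_adenoma"] * 4
    _, pvals = univariate_filter(table, labels, alpha=0.05)
    expected = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
    assert pvals["f"] == pytest.approx(expected, abs=1e-12)


# ---------------------------------------------------------------------------
# RFE

def test_rfe_keeps_ceil_fraction_and_is_deterministic(rng):
    n = 60
    labels = ["adenoma"] * 30 + ["non_adenoma"] * 30
    table = pd.DataFrame(rng.normal(size=(n, 20)),
                         columns=[f"f{i}" for i in range(20)])
    got = rfe_select(table, labels, keep_frac=0.30, seed=1)
    assert len(got) == 6  # ceil(0.3 * 20)
    assert got == rfe_select(table, labels, keep_frac=0.30, seed=1)


def test_rfe_retains_perfect_separator(rng):
    n = 40
    y = np.r_[np.ones(20), np.zeros(20)]
    labels = ["adenoma" if v else "non_adenoma" for v in y]
    table = pd.DataFrame(rng.normal(size=(n, 10)),
                         columns=[f"f{i}" for i in range(10)])
    table["f0"] = y * 4 + rng.normal(scale=0.1, size=n)
    assert "f0" in rfe_select(table, labels, keep_frac=0.30, seed=0)


# ---------------------------------------------------------------------------
# LASSO 1-SE

def _informative_table(rng, n=200, noise_features=10, effect=3.0):
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    cols = {"signal": y * effect + rng.normal(size=n)}
    for i in range(noise_features):
        cols[f"noise{i}"] = rng.normal(size=n)
    labels = ["adenoma" if v else "non_adenoma" for v in y]
    return pd.DataFrame(cols), labels


def test_lasso_keeps_informative_zeroes_noise(rng):
    table, labels = _informative_table(rng)
    result = lasso_1se(table, labels, folds=10, seed=3)
    assert "signal" in result.survivors
    zeroed = sum(result.coefficients[f"noise{i}"] == 0.0 for i in range(10))
    assert zeroed >= 8


def test_lasso_row_duplication_keeps_survivors(rng):
    table, labels = _informative_table(rng, n=100, noise_features=5)
    base = lasso_1se(table, labels, folds=5, seed=7)
    doubled = pd.concat([table, table], ignore_index=True)
    dup = lasso_1se(doubled, labels + labels, folds=5, seed=7)
    assert set(base.survivors) <= set(dup.survivors) or set(dup.survivors) <= set(base.survivors)
    assert "signal" in dup.survivors


def test_lasso_zero_variance_feature_gets_zero_coefficient(rng):
    table, labels = _informative_table(rng, n=100, noise_features=3)
    table["flat"] = 1.0
    result = lasso_1se(table, labels, folds=5, seed=0)
    assert result.coefficients["flat"] == 0.0


# ---------------------------------------------------------------------------
# model fit / score

def test_score_closed_form():
    model = RadiomicsModel(
        feature_names=["f"], intercept=0.0, coefficients=np.array([1.0]),
        standardize_mean=np.array([0.0]), standardize_sd=np.array([1.0]))
    row = {"f": 2.0}
    assert model.score(row) == pytest.approx(2.0)
    table = pd.DataFrame({"f": [2.0]})
    assert model.predict_proba(table).iloc[0] == pytest.approx(1 / (1 + np.exp(-2.0)))


def test_fit_balanced_symmetric_problem_has_small_intercept(rng):
    n = 400
    y = np.r_[np.ones(n // 2), np.zeros(n // 2)]
    labels = ["adenoma" if v else "non_adenoma" for v in y]
    table = pd.DataFrame({"f": np.where(y == 1, 1.0, -1.0) + rng.normal(size=n)})
    model = fit_model(table, labels, ["f"])
    assert abs(model.intercept) < 0.35  # ~3 standard errors for this design


def test_scoring_training_data_reproduces_linear_predictor(rng):
    table, labels = _informative_table(rng, n=80, noise_features=3)
    model = fit_model(table, labels, ["signal", "noise0"])
    scores = model.score_table(table)
    for i in range(5):
        assert scores.iloc[i] == pytest.approx(model.score(table.iloc[i]), abs=1e-12)


def test_model_json_roundtrip(rng, tmp_path):
    table, labels = _informative_table(rng, n=60, noise_features=2)
    model = fit_model(table, labels, ["signal"])
    path = tmp_path / "model.json"
    model.to_json(path)
    back = RadiomicsModel.from_json(path)
    pd.testing.assert_series_equal(back.score_table(table), model.score_table(table))


# ---------------------------------------------------------------------------
# split

def test_split_237_gives_189_48():
    ids = [f"c{i}" for i in range(237)]
    labels = ["adenoma"] * 135 + ["non_adenoma"] * 102
    train, val = split_train_val(ids, labels, ratio=0.8, seed=0)
    assert len(train) == 189
    assert len(val) == 48
    assert set(train) | set(val) == set(ids)
    assert set(train) & set(val) == set()


def test_split_is_stratified_and_seed_deterministic():
    ids = list(range(100))
    labels = ["adenoma"] * 60 + ["non_adenoma"] * 40
    t1, v1 = split_train_val(ids, labels, ratio=0.8, seed=5)
    t2, v2 = split_train_val(ids, labels, ratio=0.8, seed=5)
    assert t1 == t2 and v1 == v2
    train_pos = sum(1 for i in t1 if labels[i] == "adenoma")
    assert train_pos == 48  # floor(0.8 * 60)
    with pytest.raises(InsufficientDataError):
        split_train_val([1, 2, 3], ["adenoma", "adenoma", "non_adenoma"])


# ---------------------------------------------------------------------------
# cascade nesting

def test_cascade_survivor_sets_are_nested(rng):
    n = 80
    y = np.r_[np.ones(40), np.zeros(40)]
    labels = ["adenoma" if v else "non_adenoma" for v in y]
    cols = {f"n{i}": rng.normal(size=n) for i in range(30)}
    for k in range(3):
        cols[f"sig{k}"] = y * 2.0 + rng.normal(size=n)
    table = pd.DataFrame(cols)
    trace = run_cascade(table, labels, seed=2)
    stages = list(trace.stages.values())
    for prev, cur in zip(stages, stages[1:]):
        assert set(cur) <= set(prev)
    assert len(trace.final) >= 1
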