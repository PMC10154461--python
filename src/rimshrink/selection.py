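"""Feature stability screening, the three-stage selection cascade, and the
logistic radiomics model.

Stages (each operating on the survivors of the previous one, so survivor
sets are nested):
  1. stability: ICC(2,1) (two-way random effects, absolute agreement,
     single rater) between paired rater-1/rater-2 extractions; features
     with ICC < 0.75 are excluded;
  2. univariate: two-sided Mann-Whitney U per feature, keep P < 0.05;
  3. RFE: recursive feature elimination with an L2-regularized logistic
     base learner on standardized features, dropping the smallest-|coef|
     feature per round until ceil(0.30 x n_in) remain;
  4. LASSO: L1-penalized logistic path with stratified 10-fold CV of the
     binomial deviance, penalty chosen by the one-standard-error rule;
     survivors are the nonzero coefficients.

The final model is a maximum-likelihood logistic regression on the
standardized survivors; the radiomics score is its linear predictor.  All
standardization constants and selection statistics are computed from
training rows only.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from scipy import stats

from .errors import (
    AlignmentError,
    ConfigError,
    DataError,
    InsufficientDataError,
)
from .io import POSITIVE_LABEL

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# ICC

def icc_2_1(rater1_values, rater2_values) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    Mean-squares form for n subjects x k=2 raters:
        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    """
    y1 = np.asarray(rater1_values, dtype=np.float64)
    y2 = np.asarray(rater2_values, dtype=np.float64)
    if y1.shape != y2.shape or y1.ndim != 1:
        raise DataError("paired rater vectors must be equal-length 1D")
    n = y1.size
    if n < 3:
        raise InsufficientDataError(f"ICC needs >= 3 subjects, got {n}")
    data = np.stack([y1, y2], axis=1)
    k = 2
    grand = data.mean()
    subj_means = data.mean(axis=1)
    rater_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = k * float(((subj_means - grand) ** 2).sum())
    ss_cols = n * float(((rater_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0.0:
        return 1.0  # identical constant vectors: perfect agreement
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0.0:
        if np.allclose(y1, y2):
            return 1.0
        raise DataError("zero total variance with non-identical raters")
    return float((msr - mse) / denom)


@dataclass
class ICCReport:
    """Per-feature ICC values and the retained set at a threshold."""

    icc: pd.Series
    threshold: float = 0.75
    n_pairs: int = 0

    @property
    def retained(self) -> list[str]:
        return list(self.icc.index[self.icc >= self.threshold])

    @property
    def excluded(self) -> list[str]:
        return list(self.icc.index[self.icc < self.threshold])

    def summary(self) -> dict:
        return {
            "threshold": self.threshold,
            "n_pairs": self.n_pairs,
            "icc_mean": float(self.icc.mean()),
            "icc_sd": float(self.icc.std(ddof=1)) if len(self.icc) > 1 else 0.0,
            "n_excluded": len(self.excluded),
        }


def stability_filter(table_rater1: pd.DataFrame, table_rater2: pd.DataFrame,
                     threshold: float = 0.75) -> ICCReport:
    """Per-feature ICC(2,1) between two raters' feature tables.

    Tables are case_id-indexed DataFrames with identical feature columns;
    the ICC uses the intersection of their case sets (the re-segmented
    subset).
    """
    if list(table_rater1.columns) != list(table_rater2.columns):
        raise AlignmentError("rater tables must share feature columns")
    common = table_rater1.index.intersection(table_rater2.index)
    if len(common) < 3:
        raise AlignmentError(
            f"rater tables share only {len(common)} cases; >= 3 required")
    t1 = table_rater1.loc[common]
    t2 = table_rater2.loc[common]
    iccs = pd.Series(
        {c: icc_2_1(t1[c].to_numpy(), t2[c].to_numpy()) for c in t1.columns},
        name="icc",
    )
    return ICCReport(icc=iccs, threshold=threshold, n_pairs=len(common))


# ---------------------------------------------------------------------------
# Univariate screen

def univariate_filter(table: pd.DataFrame, labels: Sequence[str],
                      alpha: float = 0.05) -> tuple[list[str], pd.Series]:
    """Two-sided Mann-Whitney U per feature; survivors have P < alpha.

    Constant features are assigned P = 1 and dropped.  Returns (survivors,
    per-feature P values).
    """
    y = np.asarray([lab == POSITIVE_LABEL for lab in labels])
    if y.sum() < 3 or (~y).sum() < 3:
        raise InsufficientDataError("each class needs >= 3 cases for the univariate screen")
    pvals = {}
    X = table.to_numpy(dtype=np.float64)
    for i, c in enumerate(table.columns):
        a, b = X[y, i], X[~y, i]
        if np.ptp(X[:, i]) == 0.0:
            pvals[c] = 1.0
            continue
        pvals[c] = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    p = pd.Series(pvals, name="p_value")
    return list(p.index[p < alpha]), p


# ---------------------------------------------------------------------------
# RFE

def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def rfe_select(table: pd.DataFrame, labels: Sequence[str],
               keep_frac: float = 0.30, seed: int = 0) -> list[str]:
    """Recursive feature elimination down to ceil(keep_frac x n_in) features.

    Base learner: L2-regularized logistic regression on standardized
    features; one feature (smallest |coefficient|) is dropped per round.
    Deterministic given the input (the seed is accepted for interface
    symmetry; the procedure has no random element).
    """
    names = list(table.columns)
    if len(names) < 2:
        raise ConfigError("RFE needs >= 2 entering features")
    n_keep = math.ceil(keep_frac * len(names))
    if n_keep < 1:
        logger.info("RFE keep target < 1; keeping exactly 1 feature")
        n_keep = 1
    y = np.asarray([lab == POSITIVE_LABEL for lab in labels], dtype=int)
    X = table.to_numpy(dtype=np.float64)
    active = list(range(len(names)))
    while len(active) > n_keep:
        Xs, _, _ = _standardize(X[:, active])
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=1000)
        clf.fit(Xs, y)
        drop = int(np.argmin(np.abs(clf.coef_[0])))
        del active[drop]
    return [names[i] for i in active]


# ---------------------------------------------------------------------------
# LASSO with the 1-SE rule

@dataclass
class LassoResult:
    survivors: list[str]
    coefficients: pd.Series
    lambda_chosen: float
    lambda_min: float
    cv_lambdas: np.ndarray
    cv_mean_deviance: np.ndarray
    cv_se_deviance: np.ndarray
    used_lambda_min_fallback: bool = False


def _binomial_deviance(y, p):
    p = np.clip(p, 1e-12, 1 - 1e-12)
    return float(-2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def _l1_path_fit(Xs, y, lam):
    """One L1 logistic fit at penalty lam (glmnet scale: lam * n = 1/C)."""
    n = len(y)
    C = 1.0 / (lam * n)
    clf = LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                             max_iter=2000, tol=1e-7)
    clf.fit(Xs, y)
    return clf


def lasso_1se(table: pd.DataFrame, labels: Sequence[str], folds: int = 10,
              seed: int = 0, n_lambdas: int = 50) -> LassoResult:
    """L1-penalized logistic path with stratified K-fold CV and the 1-SE rule.

    Features are standardized to zero mean / unit sd first.  The chosen
    penalty is the largest lambda whose mean CV deviance is within one
    standard error of the minimum.  If the chosen lambda zeroes every
    coefficient, lambda_min is used instead (logged).
    """
    names = list(table.columns)
    if len(names) < 2:
        raise ConfigError("LASSO needs >= 2 entering features")
    y = np.asarray([lab == POSITIVE_LABEL for lab in labels], dtype=int)
    if y.sum() < folds or (1 - y).sum() < folds:
        folds = max(2, min(int(y.sum()), int((1 - y).sum())))
        logger.info("reducing CV folds to %d to keep both classes in every fold", folds)
    X = table.to_numpy(dtype=np.float64)
    Xs, _, _ = _standardize(X)
    n = len(y)
    ybar = y.mean()
    lam_max = float(np.max(np.abs(Xs.T @ (y - ybar))) / n)
    lambdas = np.logspace(np.log10(lam_max), np.log10(lam_max * 1e-3), n_lambdas)

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    dev = np.zeros((folds, n_lambdas))
    for f, (tr, te) in enumerate(cv.split(Xs, y)):
        Xtr, mean, sd = _standardize(X[tr])
        Xte = (X[te] - mean) / sd  # training-fold standardization, no leakage
        for li, lam in enumerate(lambdas):
            clf = _l1_path_fit(Xtr, y[tr], lam)
            p = clf.predict_proba(Xte)[:, 1]
            dev[f, li] = _binomial_deviance(y[te], p)
    mean_dev = dev.mean(axis=0)
    se_dev = dev.std(axis=0, ddof=1) / np.sqrt(folds)
    i_min = int(np.argmin(mean_dev))
    lambda_min = float(lambdas[i_min])
    within = mean_dev <= mean_dev[i_min] + se_dev[i_min]
    i_1se = int(np.argmax(within))  # lambdas are decreasing: first hit = largest
    lambda_1se = float(lambdas[i_1se])

    clf = _l1_path_fit(Xs, y, lambda_1se)
    coefs = clf.coef_[0]
    fallback = False
    if not np.any(coefs != 0.0):
        logger.info("1-SE lambda zeroed all coefficients; falling back to lambda_min")
        clf = _l1_path_fit(Xs, y, lambda_min)
        coefs = clf.coef_[0]
        lambda_1se = lambda_min
        fallback = True
    coef_series = pd.Series(coefs, index=names, name="lasso_coef")
    return LassoResult(
        survivors=[nm for nm, c in coef_series.items() if c != 0.0],
        coefficients=coef_series,
        lambda_chosen=lambda_1se,
        lambda_min=lambda_min,
        cv_lambdas=lambdas,
        cv_mean_deviance=mean_dev,
        cv_se_deviance=se_dev,
        used_lambda_min_fallback=fallback,
    )


# ---------------------------------------------------------------------------
# Selection trace

@dataclass
class SelectionTrace:
    """Ordered record of survivors after each cascade stage."""

    stages: "dict[str, list[str]]" = field(default_factory=dict)
    p_values: Optional[pd.Series] = None
    icc_report: Optional[ICCReport] = None
    lasso: Optional[LassoResult] = None

    def record(self, stage: str, survivors: Sequence[str]):
        prev = list(self.stages.values())[-1] if self.stages else None
        if prev is not None and not set(survivors) <= set(prev):
            raise DataError(f"stage {stage!r} survivors are not nested in the previous stage")
        self.stages[stage] = list(survivors)

    @property
    def final(self) -> list[str]:
        return list(self.stages.values())[-1] if self.stages else []

    def to_json(self, path=None) -> str:
        payload = {
            "stages": self.stages,
            "lambda_chosen": self.lasso.lambda_chosen if self.lasso else None,
            "lambda_min": self.lasso.lambda_min if self.lasso else None,
            "lasso_coefficients": (
                {k: float(v) for k, v in self.lasso.coefficients.items() if v != 0.0}
                if self.lasso else None),
            "icc": self.icc_report.summary() if self.icc_report else None,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_cascade(train_table: pd.DataFrame, train_labels: Sequence[str],
                icc_report: Optional[ICCReport] = None,
                icc_threshold: float = 0.75, alpha: float = 0.05,
                keep_frac: float = 0.30, folds: int = 10,
                seed: int = 0) -> SelectionTrace:
    """Full cascade: stability -> univariate -> RFE -> LASSO.

    icc_report may come from any paired rater subset; when None the
    stability stage is skipped (all features pass).
    """
    trace = SelectionTrace(icc_report=icc_report)
    names = list(train_table.columns)
    trace.record("input", names)
    if icc_report is not None:
        stable = [n for n in names if n in set(icc_report.retained)]
        trace.record("stability", stable)
    else:
        stable = names
        trace.record("stability", stable)
    if len(stable) == 0:
        raise InsufficientDataError("no features survived the stability screen")
    survivors, pvals = univariate_filter(train_table[stable], train_labels, alpha=alpha)
    trace.p_values = pvals
    trace.record("univariate", survivors)
    if len(survivors) == 0:
        raise InsufficientDataError("no features survived the univariate screen")
    if len(survivors) > 1:
        survivors = rfe_select(train_table[survivors], train_labels,
                               keep_frac=keep_frac, seed=seed)
    trace.record("rfe", survivors)
    if len(survivors) > 1:
        lasso = lasso_1se(train_table[survivors], train_labels, folds=folds, seed=seed)
        trace.lasso = lasso
        final = lasso.survivors if lasso.survivors else survivors
    else:
        final = survivors
    trace.record("lasso", final)
    return trace


# ---------------------------------------------------------------------------
# Logistic model and radiomics score

@dataclass
class RadiomicsModel:
    feature_names: list[str]
    intercept: float
    coefficients: np.ndarray
    standardize_mean: np.ndarray
    standardize_sd: np.ndarray
    seed: int = 0
    train_ids: list = field(default_factory=list)
    ridge_stabilized: bool = False

    def score(self, row) -> float:
        """Radiomics score: the linear predictor for one case."""
        x = np.asarray([row[n] for n in self.feature_names], dtype=np.float64)
        z = (x - self.standardize_mean) / self.standardize_sd
        return float(self.intercept + z @ self.coefficients)

    def score_table(self, table: pd.DataFrame) -> pd.Series:
        X = table[self.feature_names].to_numpy(dtype=np.float64)
        Z = (X - self.standardize_mean) / self.standardize_sd
        return pd.Series(self.intercept + Z @ self.coefficients,
                         index=table.index, name="radiomics_score")

    def predict_proba(self, table: pd.DataFrame) -> pd.Series:
        s = self.score_table(table)
        return pd.Series(1.0 / (1.0 + np.exp(-s)), index=s.index, name="probability")

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": self.feature_names,
            "intercept": self.intercept,
            "coefficients": self.coefficients.tolist(),
            "standardize_mean": self.standardize_mean.tolist(),
            "standardize_sd": self.standardize_sd.tolist(),
            "seed": self.seed,
            "train_ids": [str(i) for i in self.train_ids],
            "ridge_stabilized": self.ridge_stabilized,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "RadiomicsModel":
        try:
            payload = json.loads(text_or_path)
        except (json.JSONDecodeError, TypeError):
            with open(text_or_path) as fh:
                payload = json.load(fh)
        return cls(
            feature_names=payload["feature_names"],
            intercept=float(payload["intercept"]),
            coefficients=np.asarray(payload["coefficients"], dtype=np.float64),
            standardize_mean=np.asarray(payload["standardize_mean"], dtype=np.float64),
            standardize_sd=np.asarray(payload["standardize_sd"], dtype=np.float64),
            seed=int(payload.get("seed", 0)),
            train_ids=payload.get("train_ids", []),
            ridge_stabilized=bool(payload.get("ridge_stabilized", False)),
        )


def fit_model(table: pd.DataFrame, labels: Sequence[str],
              survivors: Sequence[str], seed: int = 0) -> RadiomicsModel:
    """Maximum-likelihood logistic fit on the standardized survivors.

    Perfect or quasi-perfect separation (diverging coefficients) falls back
    to a lightly ridge-penalized fit, logged.
    """
    survivors = list(survivors)
    if not survivors:
        raise ConfigError("cannot fit a model with no surviving features")
    y = np.asarray([lab == POSITIVE_LABEL for lab in labels], dtype=int)
    X = table[survivors].to_numpy(dtype=np.float64)
    Z, mean, sd = _standardize(X)
    # near-unpenalized ML fit; C huge so the penalty is numerically inert
    clf = LogisticRegression(C=1e8, solver="lbfgs", max_iter=5000)
    clf.fit(Z, y)
    ridge = False
    if np.any(np.abs(clf.coef_[0]) > 30.0) or np.abs(clf.intercept_[0]) > 30.0:
        logger.info("separation detected; refitting with a small L2 penalty")
        clf = LogisticRegression(C=1.0, solver="lbfgs", max_iter=5000)
        clf.fit(Z, y)
        ridge = True
    return RadiomicsModel(
        feature_names=survivors,
        intercept=float(clf.intercept_[0]),
        coefficients=clf.coef_[0].astype(np.float64),
        standardize_mean=mean,
        standardize_sd=sd,
        seed=seed,
        train_ids=list(table.index),
        ridge_stabilized=ridge,
    )


# ---------------------------------------------------------------------------
# Train / validation split

def split_train_val(case_ids: Sequence, labels: Sequence[str],
                    ratio: float = 0.8, seed: int = 0) -> tuple[list, list]:
    """Stratified random split with train size = floor(ratio x n).

    Per-class train counts start at floor(ratio x n_c) and the remainder up
    to the overall floor(ratio x n) goes to classes by largest fractional
    remainder (ties by class name).  Disjoint and exhaustive.
    """
    case_ids = list(case_ids)
    labels = list(labels)
    n = len(case_ids)
    if n < 5:
        raise InsufficientDataError(f"split needs >= 5 cases, got {n}")
    if not 0 < ratio < 1:
        raise ConfigError(f"split ratio must be in (0,1), got {ratio}")
    classes = sorted(set(labels))
    for c in classes:
        if labels.count(c) < 2:
            raise InsufficientDataError(f"class {c!r} has < 2 members; cannot stratify")
    target_train = math.floor(ratio * n)
    base = {c: math.floor(ratio * labels.count(c)) for c in classes}
    rem = {c: ratio * labels.count(c) - base[c] for c in classes}
    short = target_train - sum(base.values())
    for c in sorted(classes, key=lambda c: (-rem[c], c))[:short]:
        base[c] += 1
    rng = np.random.default_rng(seed)
    train_ids, val_ids = [], []
    for c in classes:
        ids_c = [i for i, lab in zip(case_ids, labels) if lab == c]
        perm = rng.permutation(len(ids_c))
        take = base[c]
        train_ids.extend(ids_c[i] for i in perm[:take])
        val_ids.extend(ids_c[i] for i in perm[take:])
    return train_ids, val_ids
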