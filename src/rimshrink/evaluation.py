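"""Discrimination and clinical-utility metrics for the four-method
comparison.

AUC uses the Mann-Whitney rank estimator with tie correction and a DeLong
95% CI.  pAUC is the unstandardized trapezoidal area under the empirical
ROC polyline restricted to specificity >= 95% (FPR in [0, 0.05], linear
interpolation at the boundary; maximum 0.05), with a stratified-bootstrap
CI.  Operating points follow either the Youden policy (ties toward higher
specificity) or the spec95 policy (smallest threshold with specificity >=
0.95).  Paired model comparisons use McNemar's test on correctness
indicators (exact binomial when discordant pairs < 25, else chi-square with
continuity correction) and Wilcoxon signed-rank on paired radiomics scores
with a Bonferroni multiplier of 6.  Decision curves report net benefit
NB(t) = TP/n - FP/n * t/(1-t) against treat-all and treat-none.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar as _sm_mcnemar

from .errors import ConfigError, DataError, InsufficientDataError
from .io import POSITIVE_LABEL

MCNEMAR_EXACT_CUTOFF = 25  # exact binomial below, chi-square with correction at/above


def _check_two_class(y: np.ndarray):
    if y.all() or not y.any():
        raise DataError("both classes must be present")


def _as_binary(labels) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "SUO":
        return np.asarray([lab == POSITIVE_LABEL for lab in labels], dtype=bool)
    return labels.astype(bool)


# ---------------------------------------------------------------------------
# ROC / AUC

def roc_points(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    """Empirical ROC polyline (FPR, TPR), one vertex per distinct score.

    Tied scores produce diagonal segments, so the trapezoidal area equals
    the tie-corrected Mann-Whitney AUC.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    _check_two_class(y)
    order = np.argsort(-scores, kind="mergesort")
    s = scores[order]
    t = y[order]
    distinct = np.r_[np.diff(s) != 0, True]
    tp = np.cumsum(t)[distinct]
    fp = np.cumsum(~t)[distinct]
    tpr = np.r_[0.0, tp / t.sum()]
    fpr = np.r_[0.0, fp / (~t).sum()]
    return fpr, tpr


def auc_mannwhitney(scores, labels) -> float:
    """Tie-corrected rank (Mann-Whitney) AUC estimate."""
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    _check_two_class(y)
    ranks = stats.rankdata(scores)
    n1 = int(y.sum())
    n0 = int((~y).sum())
    u = ranks[y].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def _delong_variance(scores, y) -> float:
    """DeLong variance of the AUC via placement values (midrank form)."""
    pos = scores[y]
    neg = scores[~y]
    m, n = len(pos), len(neg)

    def _placements(a, b):
        # for each a_i: P(b < a_i) + 0.5 P(b == a_i)
        order = np.sort(b)
        lo = np.searchsorted(order, a, side="left")
        hi = np.searchsorted(order, a, side="right")
        return (lo + 0.5 * (hi - lo)) / len(b)

    v10 = _placements(pos, neg)
    v01 = 1.0 - _placements(neg, pos)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return s10 / m + s01 / n


def roc_auc(scores, labels, alpha: float = 0.05) -> dict:
    """AUC with a DeLong 95% CI (clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    _check_two_class(y)
    auc = auc_mannwhitney(scores, y)
    var = _delong_variance(scores, y)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(var)
    return {"auc": auc, "ci_low": float(np.clip(auc - half, 0, 1)),
            "ci_high": float(np.clip(auc + half, 0, 1))}


def _pauc_from_points(fpr: np.ndarray, tpr: np.ndarray, max_fpr: float) -> float:
    """Trapezoidal area under the ROC polyline over FPR in [0, max_fpr].

    The polyline is clipped exactly: vertices beyond the boundary are
    replaced by the linear interpolation on the crossing segment.  Vertical
    segments (repeated FPR) contribute zero width and need no special
    handling under the trapezoid rule.
    """
    beyond = np.flatnonzero(fpr > max_fpr)
    if len(beyond) == 0:
        return float(np.trapezoid(tpr, fpr))
    k = beyond[0]  # first vertex past the boundary; k >= 1 since fpr[0] = 0
    f1, f2 = fpr[k - 1], fpr[k]
    t_b = tpr[k - 1] + (tpr[k] - tpr[k - 1]) * (max_fpr - f1) / (f2 - f1)
    fpr_c = np.r_[fpr[:k], max_fpr]
    tpr_c = np.r_[tpr[:k], t_b]
    return float(np.trapezoid(tpr_c, fpr_c))


def pauc_high_spec(scores, labels, min_spec: float = 0.95,
                   n_boot: int = 2000, seed: int = 0) -> dict:
    """Unstandardized pAUC over specificity in [min_spec, 1].

    CI by stratified bootstrap (resampling within each class), seeded.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    _check_two_class(y)
    max_fpr = 1.0 - min_spec
    fpr, tpr = roc_points(scores, y)
    pauc = _pauc_from_points(fpr, tpr, max_fpr)
    rng = np.random.default_rng(seed)
    pos_idx = np.flatnonzero(y)
    neg_idx = np.flatnonzero(~y)
    boot = np.empty(n_boot)
    for b in range(n_boot):
        take = np.r_[rng.choice(pos_idx, len(pos_idx)), rng.choice(neg_idx, len(neg_idx))]
        f, t = roc_points(scores[take], y[take])
        boot[b] = _pauc_from_points(f, t, max_fpr)
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {"pauc": pauc, "ci_low": float(lo), "ci_high": float(hi),
            "max_fpr": max_fpr}


# ---------------------------------------------------------------------------
# Operating points

def operating_point(scores, labels, policy: str = "youden") -> dict:
    """(threshold, sensitivity, specificity, accuracy) under a policy.

    Predicted positive means score >= threshold.  "youden" maximizes
    sens + spec - 1 with ties broken toward higher specificity (then the
    higher threshold); "spec95" takes the smallest threshold achieving
    specificity >= 0.95.
    """
    scores = np.asarray(scores, dtype=np.float64)
    y = _as_binary(labels)
    _check_two_class(y)
    if policy not in ("youden", "spec95"):
        raise ConfigError(f"unknown operating-point policy {policy!r}")
    # candidate thresholds: each distinct score plus one above the maximum
    uniq = np.unique(scores)
    candidates = np.r_[uniq, uniq[-1] + 1.0]
    n1 = y.sum()
    n0 = (~y).sum()
    best = None
    for thr in candidates:
        pred = scores >= thr
        sens = float((pred & y).sum() / n1)
        spec = float((~pred & ~y).sum() / n0)
        acc = float((pred == y).mean())
        if policy == "youden":
            key = (sens + spec - 1.0, spec, thr)
            if best is None or key > best[0]:
                best = (key, thr, sens, spec, acc)
        else:
            if spec >= 0.95 and best is None:
                best = (None, thr, sens, spec, acc)
    if policy == "spec95" and best is None:  # unreachable: thr above max gives spec 1
        raise DataError("no threshold achieves specificity >= 0.95")
    _, thr, sens, spec, acc = best
    return {"threshold": float(thr), "sensitivity": sens, "specificity": spec,
            "accuracy": acc}


# ---------------------------------------------------------------------------
# Paired tests

def mcnemar_test(pred_a, pred_b, labels) -> float:
    """McNemar P for paired correctness of two classifiers on the same cases.

    pred_a/pred_b are predicted-positive indicators; correctness is
    measured against labels.  Exact binomial when discordant pairs b+c <
    25, else chi-square with continuity correction; b+c = 0 gives P = 1.
    """
    y = _as_binary(labels)
    a_ok = np.asarray(pred_a, dtype=bool) == y
    b_ok = np.asarray(pred_b, dtype=bool) == y
    b_cnt = int((a_ok & ~b_ok).sum())
    c_cnt = int((~a_ok & b_ok).sum())
    if b_cnt + c_cnt == 0:
        return 1.0
    table = [[int((a_ok & b_ok).sum()), b_cnt], [c_cnt, int((~a_ok & ~b_ok).sum())]]
    exact = (b_cnt + c_cnt) < MCNEMAR_EXACT_CUTOFF
    res = _sm_mcnemar(table, exact=exact, correction=True)
    return float(min(res.pvalue, 1.0))


def compare_scores(score_sets: dict[str, Sequence[float]], group_labels) -> pd.DataFrame:
    """Pairwise Wilcoxon signed-rank on paired scores, Bonferroni x 6.

    Within each class, the 6 method pairs are tested two-sided on paired
    per-case scores; adjusted P = min(1, 6 x raw P).
    """
    methods = sorted(score_sets)
    if len(methods) < 2:
        raise ConfigError("need >= 2 methods to compare")
    y = _as_binary(group_labels)
    n_pairs = len(list(itertools.combinations(methods, 2)))
    rows = []
    for cls_name, cls_mask in (("positive", y), ("negative", ~y)):
        for a, b in itertools.combinations(methods, 2):
            sa = np.asarray(score_sets[a], dtype=np.float64)[cls_mask]
            sb = np.asarray(score_sets[b], dtype=np.float64)[cls_mask]
            if len(sa) < 5:
                raise InsufficientDataError(
                    f"fewer than 5 paired cases in class {cls_name!r}")
            diff = sa - sb
            if np.allclose(diff, 0.0):
                raw = 1.0
            else:
                raw = float(stats.wilcoxon(sa, sb, alternative="two-sided",
                                           zero_method="wilcox").pvalue)
            rows.append({
                "class": cls_name, "method_a": a, "method_b": b,
                "p_raw": raw, "p_adjusted": min(1.0, n_pairs * raw),
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Decision curve analysis

def decision_curve(probabilities, labels, thresholds=None) -> pd.DataFrame:
    """Net benefit of the model vs treat-all / treat-none on a threshold grid.

    NB_model(t) = TP(t)/n - FP(t)/n * t/(1-t) with predicted positive
    meaning probability >= t; NB_all(t) = pi - (1-pi) t/(1-t); treat-none
    is identically 0.  t = 1 is excluded from the grid.
    """
    p = np.asarray(probabilities, dtype=np.float64)
    if np.any((p < 0) | (p > 1)):
        raise DataError("probabilities must lie in [0, 1]")
    y = _as_binary(labels)
    if thresholds is None:
        thresholds = np.round(np.arange(0.01, 1.0, 0.01), 10)
    thresholds = np.asarray(thresholds, dtype=np.float64)
    if np.any(thresholds >= 1.0) or np.any(thresholds <= 0.0):
        raise ConfigError("thresholds must lie strictly inside (0, 1)")
    n = len(y)
    prev = y.mean()
    rows = []
    for t in thresholds:
        pred = p >= t
        tp = float((pred & y).sum()) / n
        fp = float((pred & ~y).sum()) / n
        odds = t / (1.0 - t)
        rows.append({
            "threshold": float(t),
            "net_benefit_model": tp - fp * odds,
            "net_benefit_all": prev - (1.0 - prev) * odds,
            "net_benefit_none": 0.0,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report assembly

@dataclass
class ROCResult:
    auc: float
    auc_ci: tuple[float, float]
    pauc: float
    pauc_ci: tuple[float, float]
    youden: dict
    spec95: dict

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "auc_ci": list(self.auc_ci),
            "pauc": self.pauc, "pauc_ci": list(self.pauc_ci),
            "youden": self.youden, "spec95": self.spec95,
        }


@dataclass
class EvalReport:
    """Per ROI method x split: ROCResult; plus pairwise tests and DCA.

    A pure function of the serialized scores and labels: every number here
    is recomputable from the `scores` payload.
    """

    roc: dict = field(default_factory=dict)  # (method, split) -> ROCResult
    mcnemar_sens: Optional[pd.DataFrame] = None
    score_comparisons: Optional[pd.DataFrame] = None
    dca: dict = field(default_factory=dict)  # method -> DataFrame
    scores: dict = field(default_factory=dict)  # (method, split) -> (scores, labels)

    def table(self, split: str) -> pd.DataFrame:
        rows = []
        for (method, sp), r in self.roc.items():
            if sp != split:
                continue
            rows.append({
                "method": method, "split": sp,
                "AUC": r.auc, "AUC_lo": r.auc_ci[0], "AUC_hi": r.auc_ci[1],
                "SEN": r.youden["sensitivity"], "SPE": r.youden["specificity"],
                "ACC": r.youden["accuracy"],
                "pAUC": r.pauc, "pAUC_lo": r.pauc_ci[0], "pAUC_hi": r.pauc_ci[1],
                "SEN_spec95": r.spec95["sensitivity"], "ACC_spec95": r.spec95["accuracy"],
            })
        return pd.DataFrame(rows).set_index("method") if rows else pd.DataFrame()

    def to_json(self, path=None) -> str:
        payload = {
            "roc": {f"{m}|{s}": r.to_dict() for (m, s), r in self.roc.items()},
            "mcnemar_sensitivity": (self.mcnemar_sens.to_dict(orient="records")
                                    if self.mcnemar_sens is not None else None),
            "score_comparisons": (self.score_comparisons.to_dict(orient="records")
                                  if self.score_comparisons is not None else None),
            "dca": {m: df.to_dict(orient="list") for m, df in self.dca.items()},
            "scores": {f"{m}|{s}": {"scores": list(map(float, sc)),
                                    "labels": [str(l) for l in lb]}
                       for (m, s), (sc, lb) in self.scores.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def run_report(scores_by_method_split: dict, pauc_seed: int = 0,
               n_boot: int = 2000) -> EvalReport:
    """Build the full report from {(method, split): (scores, labels)}.

    The spec95 operating point (and the McNemar sensitivity comparison at
    it) is computed on the pooled sample per method, i.e. all splits
    concatenated, matching the all-samples framing of the headline pAUC
    numbers; per-split tables use per-split thresholds.
    """
    report = EvalReport(scores=dict(scores_by_method_split))
    methods = sorted({m for m, _ in scores_by_method_split})
    splits = sorted({s for _, s in scores_by_method_split})
    for (method, split), (sc, lb) in scores_by_method_split.items():
        y = _as_binary(lb)
        _check_two_class(y)
        a = roc_auc(sc, y)
        p = pauc_high_spec(sc, y, seed=pauc_seed, n_boot=n_boot)
        report.roc[(method, split)] = ROCResult(
            auc=a["auc"], auc_ci=(a["ci_low"], a["ci_high"]),
            pauc=p["pauc"], pauc_ci=(p["ci_low"], p["ci_high"]),
            youden=operating_point(sc, y, "youden"),
            spec95=operating_point(sc, y, "spec95"),
        )
    # pooled-sample pairwise comparisons
    pooled = {}
    pooled_labels = None
    for method in methods:
        parts, labs = [], []
        for split in splits:
            if (method, split) in scores_by_method_split:
                sc, lb = scores_by_method_split[(method, split)]
                parts.append(np.asarray(sc, dtype=np.float64))
                labs.append(_as_binary(lb))
        pooled[method] = np.concatenate(parts)
        pooled_labels = np.concatenate(labs)
    if len(methods) >= 2 and pooled_labels is not None:
        rows = []
        preds = {}
        for method in methods:
            op = operating_point(pooled[method], pooled_labels, "spec95")
            preds[method] = pooled[method] >= op["threshold"]
        pos = pooled_labels
        for a_m, b_m in itertools.combinations(methods, 2):
            p_val = mcnemar_test(preds[a_m][pos], preds[b_m][pos], np.ones(pos.sum(), bool))
            rows.append({"method_a": a_m, "method_b": b_m, "p_value": p_val})
        report.mcnemar_sens = pd.DataFrame(rows)
        report.score_comparisons = compare_scores(pooled, pooled_labels)
        for method in methods:
            prob = 1.0 / (1.0 + np.exp(-pooled[method]))
            report.dca[method] = decision_curve(prob, pooled_labels)
    return report
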