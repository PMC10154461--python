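"""End-to-end orchestration: phantom (or manifest) -> ROI derivation ->
feature extraction -> stability + selection cascade -> logistic model ->
evaluation report.

Design rules enforced here:
  * paired design — a case whose eroded ROI comes out empty is excluded
    from all four method tables jointly (and logged), keeping McNemar /
    Wilcoxon pairing valid;
  * leakage guard — the univariate/RFE/LASSO statistics, standardization
    constants and the model fit use training rows only; the ICC stability
    screen uses a label-free paired-rater subset (mirroring re-segmentation
    of a random sample);
  * reproducibility — everything derives from the master seed; the run
    manifest records the config snapshot and sha256 hashes of all written
    artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .errors import EmptyROIError, InsufficientDataError
from .evaluation import EvalReport, run_report
from .features import PreprocessConfig, extract_all
from .io import FeatureTable, LesionCase, load_manifest, write_feature_table
from .phantom import PhantomConfig, generate_cohort
from .roi import ROI_METHODS, derive_rois
from .selection import (
    ICCReport,
    RadiomicsModel,
    SelectionTrace,
    fit_model,
    run_cascade,
    split_train_val,
    stability_filter,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionConfig:
    icc_threshold: float = 0.75
    alpha: float = 0.05
    keep_frac: float = 0.30
    folds: int = 10


@dataclass
class RunConfig:
    """Full pipeline configuration; defaults are the published constants
    (3 mm erosion, 25 HU bins, 3x3x3 mm grid, ICC 0.75, P<0.05, 30% RFE,
    tenfold CV, 8:2 split, spec >= 95% pAUC)."""

    phantom: PhantomConfig = field(default_factory=PhantomConfig)
    manifest_path: Optional[str] = None  # when set, cases are loaded, not generated
    n_per_class: int = 60
    erosion_radius_mm: float = 3.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    split_ratio: float = 0.8
    n_rater2: int = 50  # size of the re-segmented ICC subset
    seed: int = 0
    n_boot: int = 2000  # pAUC bootstrap replicates
    out_dir: Optional[str] = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["version"] = __version__
        return d


@dataclass
class RunResult:
    config: RunConfig
    feature_tables: dict  # method -> DataFrame (case_id index, rater 1)
    icc_reports: dict  # method -> ICCReport
    traces: dict  # method -> SelectionTrace
    models: dict  # method -> RadiomicsModel
    report: EvalReport
    train_ids: list
    val_ids: list
    labels: dict  # case_id -> label
    excluded_cases: list
    manifest: dict = field(default_factory=dict)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _collect_cases(config: RunConfig) -> list[LesionCase]:
    if config.manifest_path is not None:
        return load_manifest(config.manifest_path)
    return list(generate_cohort(config.phantom, config.n_per_class, config.seed))


def run_all(config: RunConfig) -> RunResult:
    """Execute the full pipeline; write artifacts when out_dir is set."""
    t0 = time.perf_counter()
    stage_log = []

    def _log_stage(name, start):
        stage_log.append({"stage": name, "seconds": round(time.perf_counter() - start, 3)})

    start = time.perf_counter()
    cases = _collect_cases(config)
    _log_stage("collect_cases", start)

    # --- ROI derivation with joint exclusion -----------------------------
    start = time.perf_counter()
    usable = []
    excluded = []
    rois1 = {}
    rois2 = {}
    for case in cases:
        try:
            rois1[case.case_id] = derive_rois(
                case.mask_rater1, case.volume.spacing,
                radius_mm=config.erosion_radius_mm, case_id=case.case_id)
        except EmptyROIError as err:
            logger.warning("excluding case %s from all four methods: %s", case.case_id, err)
            excluded.append(case.case_id)
            continue
        usable.append(case)
    if len(usable) < 10:
        raise InsufficientDataError(f"only {len(usable)} usable cases (< 10)")
    _log_stage("derive_rois", start)

    # --- rater-2 subset for the stability screen -------------------------
    rng = np.random.default_rng(config.seed)
    with_r2 = [c for c in usable if c.mask_rater2 is not None]
    n_sub = min(config.n_rater2, len(with_r2))
    subset = [with_r2[i] for i in rng.permutation(len(with_r2))[:n_sub]] if n_sub else []
    for case in subset:
        try:
            rois2[case.case_id] = derive_rois(
                case.mask_rater2, case.volume.spacing,
                radius_mm=config.erosion_radius_mm, case_id=case.case_id)
        except EmptyROIError as err:
            logger.warning("rater-2 ROI failed for %s; dropping from ICC subset: %s",
                           case.case_id, err)

    # --- feature extraction ----------------------------------------------
    start = time.perf_counter()
    tables1: dict[str, dict] = {m: {} for m in ROI_METHODS}
    tables2: dict[str, dict] = {m: {} for m in ROI_METHODS}
    for case in usable:
        for method in ROI_METHODS:
            tables1[method][case.case_id] = extract_all(
                case.volume, rois1[case.case_id][method], config.preprocess)
    for case in subset:
        if case.case_id not in rois2:
            continue
        for method in ROI_METHODS:
            tables2[method][case.case_id] = extract_all(
                case.volume, rois2[case.case_id][method], config.preprocess)
    feature_tables = {m: pd.DataFrame.from_dict(tables1[m], orient="index")
                      for m in ROI_METHODS}
    for df in feature_tables.values():
        df.index.name = "case_id"
    rater2_tables = {m: pd.DataFrame.from_dict(tables2[m], orient="index")
                     for m in ROI_METHODS}
    _log_stage("extract_features", start)

    labels = {c.case_id: c.label for c in usable}
    ids = [c.case_id for c in usable]
    label_list = [labels[i] for i in ids]

    # --- split, stability, cascade, fit ----------------------------------
    start = time.perf_counter()
    train_ids, val_ids = split_train_val(ids, label_list,
                                         ratio=config.split_ratio, seed=config.seed)
    icc_reports: dict[str, ICCReport] = {}
    traces: dict[str, SelectionTrace] = {}
    models: dict[str, RadiomicsModel] = {}
    scores_payload = {}
    for method in ROI_METHODS:
        table = feature_tables[method]
        icc = None
        if len(rater2_tables[method]) >= 3:
            icc = stability_filter(table, rater2_tables[method],
                                   threshold=config.selection.icc_threshold)
            icc_reports[method] = icc
        train_tab = table.loc[train_ids]
        train_labs = [labels[i] for i in train_ids]
        trace = run_cascade(
            train_tab, train_labs, icc_report=icc,
            icc_threshold=config.selection.icc_threshold,
            alpha=config.selection.alpha, keep_frac=config.selection.keep_frac,
            folds=config.selection.folds, seed=config.seed)
        traces[method] = trace
        model = fit_model(train_tab, train_labs, trace.final, seed=config.seed)
        models[method] = model
        for split_name, split_ids in (("train", train_ids), ("validation", val_ids)):
            sc = model.score_table(table.loc[split_ids]).to_numpy()
            lb = [labels[i] for i in split_ids]
            scores_payload[(method, split_name)] = (sc, lb)
    _log_stage("select_and_fit", start)

    # --- evaluation -------------------------------------------------------
    start = time.perf_counter()
    report = run_report(scores_payload, pauc_seed=config.seed, n_boot=config.n_boot)
    _log_stage("evaluate", start)

    result = RunResult(
        config=config, feature_tables=feature_tables, icc_reports=icc_reports,
        traces=traces, models=models, report=report,
        train_ids=train_ids, val_ids=val_ids, labels=labels,
        excluded_cases=excluded,
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written = []
        for method in ROI_METHODS:
            df = feature_tables[method].copy()
            df["roi_method"] = method
            df = df.reset_index().set_index(["case_id", "roi_method"])
            p = out / f"features_{method}.csv"
            write_feature_table(FeatureTable(data=df), p)
            written.append(p)
            p = out / f"trace_{method}.json"
            traces[method].to_json(p)
            written.append(p)
            p = out / f"model_{method}.json"
            models[method].to_json(p)
            written.append(p)
        p = out / "eval_report.json"
        report.to_json(p)
        written.append(p)
        manifest = {
            "config": config.to_dict(),
            "version": __version__,
            "excluded_cases": excluded,
            "train_ids": [str(i) for i in train_ids],
            "val_ids": [str(i) for i in val_ids],
            "stage_log": stage_log,
            "total_seconds": round(time.perf_counter() - t0, 3),
            "artifact_hashes": {pp.name: _sha256(pp) for pp in written},
        }
        with open(out / "run_manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        result.manifest = manifest
    return result


def compare_methods(result: RunResult) -> dict:
    """Rank the four methods by hold-out AUC and by pooled-sample pAUC."""
    auc_val = {m: result.report.roc[(m, "validation")].auc for m in ROI_METHODS}
    # pooled pAUC: recompute from the serialized scores (train + validation)
    from .evaluation import pauc_high_spec

    pauc_pooled = {}
    for m in ROI_METHODS:
        sc = np.r_[result.report.scores[(m, "train")][0],
                   result.report.scores[(m, "validation")][0]]
        lb = (list(result.report.scores[(m, "train")][1])
              + list(result.report.scores[(m, "validation")][1]))
        pauc_pooled[m] = pauc_high_spec(sc, lb, n_boot=10, seed=result.config.seed)["pauc"]
    rank_auc = sorted(auc_val, key=auc_val.get, reverse=True)
    rank_pauc = sorted(pauc_pooled, key=pauc_pooled.get, reverse=True)
    return {
        "auc_validation": auc_val,
        "pauc_pooled": pauc_pooled,
        "ranking_by_auc": rank_auc,
        "ranking_by_pauc": rank_pauc,
        "winner_by_auc": rank_auc[0],
        "winner_by_pauc": rank_pauc[0],
    }
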