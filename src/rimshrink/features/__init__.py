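"""Radiomics feature extraction: preprocessing plus the fixed 104-feature
vector (18 first-order, 14 shape, 72 texture) per (case, ROI method).

Pipeline order: optional window clamp -> nearest-neighbour resampling to
the target grid (default 3x3x3 mm) -> fixed-bin-width discretization
(default 25 HU) -> feature computation on the raw image only (no filtered
channels).  Extraction is fully deterministic.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np
import pandas as pd

from ..errors import EmptyROIError, IntegrityError
from ..io import CTVolume, FeatureTable, LesionCase, LesionMask
from .firstorder import first_order
from .preprocess import GreyLevelROI, PreprocessConfig, apply_window, discretize, resample_nn
from .registry import (
    CLASS_SIZES,
    TOTAL_FEATURES,
    feature_names,
    load_registry,
    names_by_class,
)
from .shape import shape_features
from .texture import texture_features

__all__ = [
    "PreprocessConfig", "GreyLevelROI", "apply_window", "resample_nn",
    "discretize", "first_order", "shape_features", "texture_features",
    "extract_all", "extract_table", "feature_names", "load_registry",
    "CLASS_SIZES", "TOTAL_FEATURES", "names_by_class",
]


def extract_all(volume: CTVolume, roi_mask: LesionMask,
                config: PreprocessConfig = PreprocessConfig()) -> "OrderedDict[str, float]":
    """Extract the full 104-feature vector for one ROI.

    Returns an ordered name -> value mapping following the registry order.
    Raises EmptyROIError if the ROI vanishes under resampling.
    """
    if config.window is not None:
        volume = apply_window(volume, *config.window)
    vol_r, mask_r = resample_nn(volume, roi_mask, config.target_spacing)
    if mask_r.num_foreground == 0:
        raise EmptyROIError("ROI empty after resampling")
    grey = discretize(vol_r, mask_r, config.bin_width)

    values = {}
    values.update(first_order(grey, vol_r.voxel_volume))
    values.update(shape_features(mask_r, vol_r.spacing))
    values.update(texture_features(grey))

    ordered = OrderedDict((name, float(values[name])) for name in feature_names())
    if len(ordered) != TOTAL_FEATURES:
        raise IntegrityError(f"expected {TOTAL_FEATURES} features, got {len(ordered)}")
    bad = [k for k, v in ordered.items() if not np.isfinite(v)]
    if bad:
        raise IntegrityError(f"non-finite feature values: {bad}")
    return ordered


def extract_table(cases_rois, config: PreprocessConfig = PreprocessConfig(),
                  rater: int = 1) -> FeatureTable:
    """Extract a FeatureTable from (case, {method: mask}) pairs.

    cases_rois: iterable of (LesionCase, dict method -> LesionMask).
    rater selects which volume/mask pairing the masks came from (metadata
    only; the masks passed in are extracted as given).
    """
    rows = []
    index = []
    for case, method_masks in cases_rois:
        for method, mask in method_masks.items():
            vec = extract_all(case.volume, mask, config)
            rows.append(vec)
            index.append((case.case_id, method))
    df = pd.DataFrame(rows, index=pd.MultiIndex.from_tuples(index, names=FeatureTable.KEY_COLS))
    return FeatureTable(data=df)
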