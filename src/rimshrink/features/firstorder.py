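"""The 18 first-order intensity statistics.

Computed on the (windowed, resampled) HU values of the ROI.  Entropy and
uniformity are computed on the fixed-bin-width discretized histogram, in
bits.  Skewness and kurtosis use population moments (kurtosis is the
Pearson form, not excess); a constant ROI has both defined as 0 by
convention, logged once.
"""

from __future__ import annotations

import logging

import numpy as np

from ..errors import EmptyROIError
from .preprocess import GreyLevelROI

logger = logging.getLogger(__name__)


def first_order(grey_roi: GreyLevelROI, voxel_volume: float) -> dict[str, float]:
    x = np.asarray(grey_roi.raw_values, dtype=np.float64)
    n = x.size
    if n == 0:
        raise EmptyROIError("first-order statistics of an empty ROI")
    mean = float(x.mean())
    dev = x - mean
    m2 = float(np.mean(dev**2))
    p10, p25, p50, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 50, 75, 90]))
    if m2 > 0:
        skew = float(np.mean(dev**3)) / m2**1.5
        kurt = float(np.mean(dev**4)) / m2**2
    else:
        logger.debug("constant ROI: skewness and kurtosis set to 0 by convention")
        skew = 0.0
        kurt = 0.0
    robust = x[(x >= p10) & (x <= p90)]
    rmad = float(np.mean(np.abs(robust - robust.mean()))) if robust.size else 0.0
    levels = grey_roi.levels
    counts = np.bincount(levels)[1:]
    p = counts[counts > 0] / n
    energy = float(np.sum(x**2))
    return {
        "firstorder_Energy": energy,
        "firstorder_TotalEnergy": voxel_volume * energy,
        "firstorder_Entropy": float(-np.sum(p * np.log2(p))),
        "firstorder_Minimum": float(x.min()),
        "firstorder_Percentile10": p10,
        "firstorder_Percentile90": p90,
        "firstorder_Maximum": float(x.max()),
        "firstorder_Mean": mean,
        "firstorder_Median": p50,
        "firstorder_InterquartileRange": p75 - p25,
        "firstorder_Range": float(x.max() - x.min()),
        "firstorder_MeanAbsoluteDeviation": float(np.mean(np.abs(dev))),
        "firstorder_RobustMeanAbsoluteDeviation": rmad,
        "firstorder_RootMeanSquared": float(np.sqrt(np.mean(x**2))),
        "firstorder_Skewness": skew,
        "firstorder_Kurtosis": kurt,
        "firstorder_Variance": m2,
        "firstorder_Uniformity": float(np.sum(p**2)),
    }
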