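"""The 72 texture features: GLCM (21), GLRLM (16), GLSZM (16), GLDM (14),
NGTDM (5).

Conventions:
  * GLCM / GLRLM: distance 1, the 13 unique 3D directions, symmetric
    co-occurrence; each feature is the unweighted mean over directions,
    skipping directions with no valid voxel pairs (GLCM) / no runs (GLRLM).
  * GLSZM zones use 26-connectivity; GLDM uses the distance-1
    26-neighbourhood with dependence tolerance 0 (equal levels); NGTDM
    neighbourhood averages use in-ROI 26-neighbours only.
  * Logs are base 2.  Degenerate inputs (single voxel, constant ROI) yield
    the documented conventions: contrast-like features 0, correlation 1
    for zero variance, NGTDM coarseness capped at 1e6.

All computations run on the zero-padded bounding-box level grid produced by
``discretize`` (pad guarantees shifted indexing stays in bounds).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import ndimage

from .preprocess import GreyLevelROI

logger = logging.getLogger(__name__)

# the 13 unique distance-1 directions of the 26-neighbourhood
DIRECTIONS = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]

COARSENESS_CAP = 1e6
_EPS = np.finfo(np.float64).eps


def _offset_views(arr: np.ndarray, offset):
    """Return (view_at_x, view_at_x_plus_offset) index slices for a step."""
    sl_a, sl_b = [], []
    for o, n in zip(offset, arr.shape):
        if o >= 0:
            sl_a.append(slice(0, n - o))
            sl_b.append(slice(o, n))
        else:
            sl_a.append(slice(-o, n))
            sl_b.append(slice(0, n + o))
    return tuple(sl_a), tuple(sl_b)


def _xlog2(p):
    return np.where(p > 0, p * np.log2(p + _EPS * (p <= 0)), 0.0)


# ---------------------------------------------------------------------------
# GLCM

def _glcm_matrix(levels, maskg, ng, offset):
    sl_a, sl_b = _offset_views(levels, offset)
    valid = maskg[sl_a] & maskg[sl_b]
    if not valid.any():
        return None
    i = levels[sl_a][valid] - 1
    j = levels[sl_b][valid] - 1
    mat = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(np.float64)
    return mat + mat.T  # symmetric co-occurrence


def _glcm_features_single(p, ng):
    i = np.arange(1, ng + 1, dtype=np.float64)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    px = p.sum(axis=1)  # == py by symmetry
    mu = float(np.sum(ii * p))
    sigma2 = float(np.sum((ii - mu) ** 2 * p))
    # p_{x+y}: k = i+j in 2..2Ng ; p_{x-y}: k = |i-j| in 0..Ng-1
    ksum = (ii + jj).astype(int)
    kdiff = np.abs(ii - jj).astype(int)
    psum = np.bincount(ksum.ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    pdiff = np.bincount(kdiff.ravel(), weights=p.ravel(), minlength=ng)
    kd = np.arange(0, ng, dtype=np.float64)
    diff_avg = float(np.sum(kd * pdiff))

    hx = float(-np.sum(_xlog2(px)))
    hxy = float(-np.sum(_xlog2(p)))
    pxpy = np.outer(px, px)
    hxy1 = float(-np.sum(p * np.log2(pxpy + _EPS * (pxpy <= 0)) * (pxpy > 0)))
    hxy2 = float(-np.sum(_xlog2(pxpy)))
    if hx > 0:
        imc1 = (hxy - hxy1) / hx
    else:
        imc1 = 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - hxy)))))

    autocorr = float(np.sum(ii * jj * p))
    if sigma2 > 0:
        correlation = (autocorr - mu * mu) / sigma2
    else:
        correlation = 1.0  # constant ROI: perfect correlation by convention

    inv_var = float(np.sum(pdiff[1:] / kd[1:] ** 2)) if ng > 1 else 0.0

    return {
        "Autocorrelation": autocorr,
        "JointAverage": mu,
        "ClusterProminence": float(np.sum((ii + jj - 2 * mu) ** 4 * p)),
        "ClusterShade": float(np.sum((ii + jj - 2 * mu) ** 3 * p)),
        "ClusterTendency": float(np.sum((ii + jj - 2 * mu) ** 2 * p)),
        "Contrast": float(np.sum((ii - jj) ** 2 * p)),
        "Correlation": correlation,
        "DifferenceAverage": diff_avg,
        "DifferenceEntropy": float(-np.sum(_xlog2(pdiff))),
        "DifferenceVariance": float(np.sum((kd - diff_avg) ** 2 * pdiff)),
        "JointEnergy": float(np.sum(p**2)),
        "JointEntropy": hxy,
        "Imc1": imc1,
        "Imc2": imc2,
        "Idm": float(np.sum(p / (1.0 + (ii - jj) ** 2))),
        "Idmn": float(np.sum(p / (1.0 + ((ii - jj) / ng) ** 2))),
        "Id": float(np.sum(p / (1.0 + np.abs(ii - jj)))),
        "Idn": float(np.sum(p / (1.0 + np.abs(ii - jj) / ng))),
        "InverseVariance": inv_var,
        "MaximumProbability": float(p.max()),
        "SumEntropy": float(-np.sum(_xlog2(psum))),
    }


GLCM_NAMES = [
    "Autocorrelation", "JointAverage", "ClusterProminence", "ClusterShade",
    "ClusterTendency", "Contrast", "Correlation", "DifferenceAverage",
    "DifferenceEntropy", "DifferenceVariance", "JointEnergy", "JointEntropy",
    "Imc1", "Imc2", "Idm", "Idmn", "Id", "Idn", "InverseVariance",
    "MaximumProbability", "SumEntropy",
]


def glcm_features(grey_roi: GreyLevelROI) -> dict[str, float]:
    levels, maskg, ng = grey_roi.level_grid, grey_roi.mask_grid, grey_roi.ng
    per_dir = []
    for offset in DIRECTIONS:
        mat = _glcm_matrix(levels, maskg, ng, offset)
        if mat is None:
            continue  # no valid voxel pairs along this direction
        per_dir.append(_glcm_features_single(mat / mat.sum(), ng))
    if not per_dir:
        logger.debug("single-voxel ROI: GLCM features set to degenerate 0")
        return {f"glcm_{n}": 0.0 for n in GLCM_NAMES}
    return {
        f"glcm_{n}": float(np.mean([d[n] for d in per_dir])) for n in GLCM_NAMES
    }


# ---------------------------------------------------------------------------
# GLRLM

def _glrlm_matrix(levels, maskg, ng, offset, max_len):
    sl_a, sl_b = _offset_views(levels, offset)
    # voxel at x starts a run iff x-offset is outside the ROI or differs in level
    same_prev = np.zeros_like(maskg)
    same_prev[sl_b] = maskg[sl_a] & maskg[sl_b] & (levels[sl_a] == levels[sl_b])
    starts = maskg & ~same_prev
    pos = np.argwhere(starts)
    if len(pos) == 0:
        return None
    lv = levels[starts]
    lengths = np.ones(len(pos), dtype=np.intp)
    off = np.asarray(offset)
    cur = pos.copy()
    alive = np.ones(len(pos), dtype=bool)
    while alive.any():
        nxt = cur[alive] + off
        ok = (maskg[nxt[:, 0], nxt[:, 1], nxt[:, 2]]
              & (levels[nxt[:, 0], nxt[:, 1], nxt[:, 2]] == lv[alive]))
        idx = np.flatnonzero(alive)
        lengths[idx[ok]] += 1
        cur[idx[ok]] = nxt[ok]
        alive[idx[~ok]] = False
    mat = np.zeros((ng, max_len), dtype=np.float64)
    np.add.at(mat, (lv - 1, lengths - 1), 1.0)
    return mat


def _weighted_matrix_features(P, n_voxels, kind):
    """Shared GLRLM/GLSZM feature formulas.

    P is counts of (grey level i, run length / zone size j); kind selects
    the name prefixes.
    """
    ng, nj = P.shape
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nj + 1, dtype=np.float64)[None, :]
    nr = P.sum()
    pr = P / nr
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    mu_i = float(np.sum(i * pr))
    mu_j = float(np.sum(j * pr))
    if kind == "glrlm":
        names = ["ShortRunEmphasis", "LongRunEmphasis", "GrayLevelNonUniformity",
                 "GrayLevelNonUniformityNormalized", "RunLengthNonUniformity",
                 "RunLengthNonUniformityNormalized", "RunPercentage",
                 "GrayLevelVariance", "RunVariance", "RunEntropy",
                 "LowGrayLevelRunEmphasis", "HighGrayLevelRunEmphasis",
                 "ShortRunLowGrayLevelEmphasis", "ShortRunHighGrayLevelEmphasis",
                 "LongRunLowGrayLevelEmphasis", "LongRunHighGrayLevelEmphasis"]
    else:
        names = ["SmallAreaEmphasis", "LargeAreaEmphasis", "GrayLevelNonUniformity",
                 "GrayLevelNonUniformityNormalized", "SizeZoneNonUniformity",
                 "SizeZoneNonUniformityNormalized", "ZonePercentage",
                 "GrayLevelVariance", "ZoneVariance", "ZoneEntropy",
                 "LowGrayLevelZoneEmphasis", "HighGrayLevelZoneEmphasis",
                 "SmallAreaLowGrayLevelEmphasis", "SmallAreaHighGrayLevelEmphasis",
                 "LargeAreaLowGrayLevelEmphasis", "LargeAreaHighGrayLevelEmphasis"]
    vals = [
        float(np.sum(P / j**2) / nr),
        float(np.sum(P * j**2) / nr),
        float(np.sum(row**2) / nr),
        float(np.sum(row**2) / nr**2),
        float(np.sum(col**2) / nr),
        float(np.sum(col**2) / nr**2),
        float(nr / n_voxels),
        float(np.sum((i - mu_i) ** 2 * pr)),
        float(np.sum((j - mu_j) ** 2 * pr)),
        float(-np.sum(_xlog2(pr))),
        float(np.sum(P / i**2) / nr),
        float(np.sum(P * i**2) / nr),
        float(np.sum(P / (i**2 * j**2)) / nr),
        float(np.sum(P * i**2 / j**2) / nr),
        float(np.sum(P * j**2 / i**2) / nr),
        float(np.sum(P * i**2 * j**2) / nr),
    ]
    return dict(zip(names, vals))


def glrlm_features(grey_roi: GreyLevelROI) -> dict[str, float]:
    levels, maskg, ng = grey_roi.level_grid, grey_roi.mask_grid, grey_roi.ng
    n_vox = grey_roi.num_voxels
    max_len = max(maskg.shape)
    per_dir = []
    for offset in DIRECTIONS:
        mat = _glrlm_matrix(levels, maskg, ng, offset, max_len)
        if mat is None:
            continue
        per_dir.append(_weighted_matrix_features(mat, n_vox, "glrlm"))
    keys = per_dir[0].keys()
    return {f"glrlm_{k}": float(np.mean([d[k] for d in per_dir])) for k in keys}


# ---------------------------------------------------------------------------
# GLSZM

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


def glszm_features(grey_roi: GreyLevelROI) -> dict[str, float]:
    levels, maskg, ng = grey_roi.level_grid, grey_roi.mask_grid, grey_roi.ng
    n_vox = grey_roi.num_voxels
    zone_rows = []
    for g in range(1, ng + 1):
        layer = levels == g
        if not layer.any():
            continue
        lab, n_zones = ndimage.label(layer, structure=_STRUCT_26)
        sizes = np.bincount(lab.ravel())[1:]
        zone_rows.extend((g, int(s)) for s in sizes)
    max_size = max(s for _, s in zone_rows)
    P = np.zeros((ng, max_size), dtype=np.float64)
    for g, s in zone_rows:
        P[g - 1, s - 1] += 1.0
    return {f"glszm_{k}": v for k, v in _weighted_matrix_features(P, n_vox, "glszm").items()}


# ---------------------------------------------------------------------------
# GLDM

def _neighbour_stacks(levels, maskg):
    """Per-voxel neighbour sums/counts/equal-level counts over the
    26-neighbourhood (both orientations of the 13 directions)."""
    nsum = np.zeros(levels.shape, dtype=np.float64)
    ncount = np.zeros(levels.shape, dtype=np.intp)
    nequal = np.zeros(levels.shape, dtype=np.intp)
    for base in DIRECTIONS:
        for offset in (base, tuple(-o for o in base)):
            sl_a, sl_b = _offset_views(levels, offset)
            valid = maskg[sl_b]
            nsum[sl_a] += levels[sl_b] * valid
            ncount[sl_a] += valid
            nequal[sl_a] += valid & (levels[sl_b] == levels[sl_a])
    return nsum, ncount, nequal


def gldm_features(grey_roi: GreyLevelROI) -> dict[str, float]:
    levels, maskg, ng = grey_roi.level_grid, grey_roi.mask_grid, grey_roi.ng
    _, _, nequal = _neighbour_stacks(levels, maskg)
    lv = levels[maskg]
    dep = nequal[maskg] + 1  # dependence size includes the centre voxel
    nd = int(dep.max())
    P = np.zeros((ng, nd), dtype=np.float64)
    np.add.at(P, (lv - 1, dep - 1), 1.0)
    nz = P.sum()
    i = np.arange(1, ng + 1, dtype=np.float64)[:, None]
    j = np.arange(1, nd + 1, dtype=np.float64)[None, :]
    p = P / nz
    mu_i = float(np.sum(i * p))
    mu_j = float(np.sum(j * p))
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    return {
        "gldm_SmallDependenceEmphasis": float(np.sum(P / j**2) / nz),
        "gldm_LargeDependenceEmphasis": float(np.sum(P * j**2) / nz),
        "gldm_GrayLevelNonUniformity": float(np.sum(row**2) / nz),
        "gldm_DependenceNonUniformity": float(np.sum(col**2) / nz),
        "gldm_DependenceNonUniformityNormalized": float(np.sum(col**2) / nz**2),
        "gldm_GrayLevelVariance": float(np.sum((i - mu_i) ** 2 * p)),
        "gldm_DependenceVariance": float(np.sum((j - mu_j) ** 2 * p)),
        "gldm_DependenceEntropy": float(-np.sum(_xlog2(p))),
        "gldm_LowGrayLevelEmphasis": float(np.sum(P / i**2) / nz),
        "gldm_HighGrayLevelEmphasis": float(np.sum(P * i**2) / nz),
        "gldm_SmallDependenceLowGrayLevelEmphasis": float(np.sum(P / (i**2 * j**2)) / nz),
        "gldm_SmallDependenceHighGrayLevelEmphasis": float(np.sum(P * i**2 / j**2) / nz),
        "gldm_LargeDependenceLowGrayLevelEmphasis": float(np.sum(P * j**2 / i**2) / nz),
        "gldm_LargeDependenceHighGrayLevelEmphasis": float(np.sum(P * i**2 * j**2) / nz),
    }


# ---------------------------------------------------------------------------
# NGTDM

def ngtdm_features(grey_roi: GreyLevelROI) -> dict[str, float]:
    levels, maskg, ng = grey_roi.level_grid, grey_roi.mask_grid, grey_roi.ng
    nsum, ncount, _ = _neighbour_stacks(levels, maskg)
    valid = maskg & (ncount > 0)
    n_valid = int(valid.sum())
    s = np.zeros(ng, dtype=np.float64)
    n_i = np.zeros(ng, dtype=np.float64)
    if n_valid:
        lv = levels[valid].astype(np.float64)
        avg = nsum[valid] / ncount[valid]
        np.add.at(s, levels[valid] - 1, np.abs(lv - avg))
        np.add.at(n_i, levels[valid] - 1, 1.0)
    p = n_i / max(n_valid, 1)
    present = p > 0
    ngp = int(present.sum())
    i_vals = np.arange(1, ng + 1, dtype=np.float64)

    denom_coarse = float(np.sum(p * s))
    if denom_coarse > 0:
        coarseness = min(1.0 / denom_coarse, COARSENESS_CAP)
    else:
        logger.debug("flat NGTDM: coarseness at cap %g", COARSENESS_CAP)
        coarseness = COARSENESS_CAP

    if ngp > 1 and n_valid:
        pi = p[present]
        ip = i_vals[present]
        si = s[present]
        dif2 = (ip[:, None] - ip[None, :]) ** 2
        contrast = (np.sum(pi[:, None] * pi[None, :] * dif2) / (ngp * (ngp - 1))
                    * np.sum(s) / n_valid)
        busy_den = float(np.sum(np.abs(ip[:, None] * pi[:, None] - ip[None, :] * pi[None, :])))
        busyness = denom_coarse / busy_den if busy_den > 0 else 0.0
        pisi = pi * si
        complexity = float(np.sum(np.abs(ip[:, None] - ip[None, :])
                                  * (pisi[:, None] + pisi[None, :])
                                  / (pi[:, None] + pi[None, :]))) / n_valid
        strength_num = float(np.sum((pi[:, None] + pi[None, :]) * dif2))
        strength = strength_num / np.sum(s) if np.sum(s) > 0 else 0.0
    else:
        contrast = busyness = complexity = strength = 0.0

    return {
        "ngtdm_Coarseness": float(coarseness),
        "ngtdm_Contrast": float(contrast),
        "ngtdm_Complexity": float(complexity),
        "ngtdm_Busyness": float(busyness),
        "ngtdm_Strength": float(strength),
    }


def texture_features(grey_roi: GreyLevelROI) -> dict[str, float]:
    """All 72 texture features for one discretized ROI."""
    out = {}
    out.update(glcm_features(grey_roi))
    out.update(glrlm_features(grey_roi))
    out.update(glszm_features(grey_roi))
    out.update(gldm_features(grey_roi))
    out.update(ngtdm_features(grey_roi))
    return out
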