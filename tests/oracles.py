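"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal textbook formulas with explicit
Python loops over voxels/pairs, deliberately avoiding the vectorized code
paths of the package so that agreement is a meaningful cross-check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

DIRECTIONS_13 = [
    (0, 0, 1), (0, 1, 0), (1, 0, 0),
    (0, 1, 1), (0, 1, -1), (1, 0, 1), (1, 0, -1), (1, 1, 0), (1, -1, 0),
    (1, 1, 1), (1, 1, -1), (1, -1, 1), (1, -1, -1),
]


# ---------------------------------------------------------------------------
# geometry

def erode_bruteforce(mask: np.ndarray, spacing, radius_mm: float,
                     mode: str = "full_3d") -> np.ndarray:
    """Scan every background voxel per foreground voxel; keep a foreground
    voxel iff its nearest background voxel centre is farther than radius."""
    mask = mask.astype(bool)
    dx, dy, dz = spacing
    out = np.zeros_like(mask)
    fg = np.argwhere(mask)
    for x, y, z in fg:
        if mode == "in_plane_2d":
            bg = np.argwhere(~mask[:, :, z])
            if len(bg) == 0:
                out[x, y, z] = True
                continue
            d2 = ((bg[:, 0] - x) * dx) ** 2 + ((bg[:, 1] - y) * dy) ** 2
        else:
            bg = np.argwhere(~mask)
            if len(bg) == 0:
                out[x, y, z] = True
                continue
            d2 = (((bg[:, 0] - x) * dx) ** 2 + ((bg[:, 1] - y) * dy) ** 2
                  + ((bg[:, 2] - z) * dz) ** 2)
        if math.sqrt(d2.min()) > radius_mm:
            out[x, y, z] = True
    return out


def resample_nn_bruteforce(values: np.ndarray, spacing, target_spacing):
    """Per-output-voxel nearest input-centre search; half-way ties resolve
    to the larger input index (the containing-interval convention)."""
    shape = values.shape
    n_out = tuple(int(np.ceil(shape[a] * spacing[a] / target_spacing[a]))
                  for a in range(3))
    out = np.empty(n_out, dtype=values.dtype)
    for j0 in range(n_out[0]):
        for j1 in range(n_out[1]):
            for j2 in range(n_out[2]):
                idx = []
                for a, j in zip(range(3), (j0, j1, j2)):
                    centre = (j + 0.5) * target_spacing[a]
                    dists = [abs(centre - (i + 0.5) * spacing[a]) for i in range(shape[a])]
                    best = min(dists)
                    # largest index among ties
                    idx.append(max(i for i, d in enumerate(dists) if d == best))
                out[j0, j1, j2] = values[idx[0], idx[1], idx[2]]
    return out


# ---------------------------------------------------------------------------
# first order

def first_order_reference(values: np.ndarray, levels: np.ndarray, voxel_volume: float):
    x = np.sort(np.asarray(values, dtype=float))
    n = len(x)
    mean = sum(x) / n
    m2 = sum((v - mean) ** 2 for v in x) / n
    m3 = sum((v - mean) ** 3 for v in x) / n
    m4 = sum((v - mean) ** 4 for v in x) / n
    p10, p25, p50, p75, p90 = np.percentile(x, [10, 25, 50, 75, 90])
    robust = [v for v in x if p10 <= v <= p90]
    rmean = sum(robust) / len(robust)
    counts = {}
    for l in levels:
        counts[l] = counts.get(l, 0) + 1
    probs = [c / n for c in counts.values()]
    return {
        "firstorder_Energy": sum(v * v for v in x),
        "firstorder_TotalEnergy": voxel_volume * sum(v * v for v in x),
        "firstorder_Entropy": -sum(p * math.log2(p) for p in probs),
        "firstorder_Minimum": x[0],
        "firstorder_Percentile10": p10,
        "firstorder_Percentile90": p90,
        "firstorder_Maximum": x[-1],
        "firstorder_Mean": mean,
        "firstorder_Median": p50,
        "firstorder_InterquartileRange": p75 - p25,
        "firstorder_Range": x[-1] - x[0],
        "firstorder_MeanAbsoluteDeviation": sum(abs(v - mean) for v in x) / n,
        "firstorder_RobustMeanAbsoluteDeviation": sum(abs(v - rmean) for v in robust) / len(robust),
        "firstorder_RootMeanSquared": math.sqrt(sum(v * v for v in x) / n),
        "firstorder_Skewness": m3 / m2**1.5 if m2 > 0 else 0.0,
        "firstorder_Kurtosis": m4 / m2**2 if m2 > 0 else 0.0,
        "firstorder_Variance": m2,
        "firstorder_Uniformity": sum(p * p for p in probs),
    }


# ---------------------------------------------------------------------------
# texture matrices, naive

def glcm_matrix_naive(levels: np.ndarray, mask: np.ndarray, ng: int, offset):
    P = np.zeros((ng, ng))
    shape = levels.shape
    for x, y, z in np.argwhere(mask):
        for sgn in (1, -1):
            nx, ny, nz = x + sgn * offset[0], y + sgn * offset[1], z + sgn * offset[2]
            if 0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]:
                if mask[nx, ny, nz]:
                    P[levels[x, y, z] - 1, levels[nx, ny, nz] - 1] += 1
    return P


def glcm_features_naive(levels, mask, ng):
    """Textbook GLCM features, averaged over the 13 directions."""
    eps = np.finfo(float).eps
    acc = {}
    n_dirs = 0
    for off in DIRECTIONS_13:
        P = glcm_matrix_naive(levels, mask, ng, off)
        if P.sum() == 0:
            continue
        n_dirs += 1
        p = P / P.sum()
        i_idx = np.arange(1, ng + 1)
        px = p.sum(axis=1)
        mu = sum(i * px_i for i, px_i in zip(i_idx, px))
        sig2 = sum((i - mu) ** 2 * px_i for i, px_i in zip(i_idx, px))
        psum = {k: 0.0 for k in range(2, 2 * ng + 1)}
        pdiff = {k: 0.0 for k in range(0, ng)}
        for a in range(ng):
            for b in range(ng):
                psum[a + b + 2] += p[a, b]
                pdiff[abs(a - b)] += p[a, b]
        da = sum(k * v for k, v in pdiff.items())
        hx = -sum(v * math.log2(v) for v in px if v > 0)
        hxy = -sum(v * math.log2(v) for v in p.ravel() if v > 0)
        hxy1 = -sum(p[a, b] * math.log2(px[a] * px[b] + eps)
                    for a in range(ng) for b in range(ng) if px[a] * px[b] > 0)
        hxy2 = -sum(px[a] * px[b] * math.log2(px[a] * px[b])
                    for a in range(ng) for b in range(ng) if px[a] * px[b] > 0)
        autoc = sum((a + 1) * (b + 1) * p[a, b] for a in range(ng) for b in range(ng))
        feats = {
            "Autocorrelation": autoc,
            "JointAverage": mu,
            "ClusterProminence": sum((a + b + 2 - 2 * mu) ** 4 * p[a, b]
                                     for a in range(ng) for b in range(ng)),
            "ClusterShade": sum((a + b + 2 - 2 * mu) ** 3 * p[a, b]
                                for a in range(ng) for b in range(ng)),
            "ClusterTendency": sum((a + b + 2 - 2 * mu) ** 2 * p[a, b]
                                   for a in range(ng) for b in range(ng)),
            "Contrast": sum((a - b) ** 2 * p[a, b] for a in range(ng) for b in range(ng)),
            "Correlation": ((autoc - mu * mu) / sig2) if sig2 > 0 else 1.0,
            "DifferenceAverage": da,
            "DifferenceEntropy": -sum(v * math.log2(v) for v in pdiff.values() if v > 0),
            "DifferenceVariance": sum((k - da) ** 2 * v for k, v in pdiff.items()),
            "JointEnergy": sum(v * v for v in p.ravel()),
            "JointEntropy": hxy,
            "Imc1": (hxy - hxy1) / hx if hx > 0 else 0.0,
            "Imc2": math.sqrt(max(0.0, 1 - math.exp(-2 * (hxy2 - hxy)))),
            "Idm": sum(p[a, b] / (1 + (a - b) ** 2) for a in range(ng) for b in range(ng)),
            "Idmn": sum(p[a, b] / (1 + ((a - b) / ng) ** 2) for a in range(ng) for b in range(ng)),
            "Id": sum(p[a, b] / (1 + abs(a - b)) for a in range(ng) for b in range(ng)),
            "Idn": sum(p[a, b] / (1 + abs(a - b) / ng) for a in range(ng) for b in range(ng)),
            "InverseVariance": sum(v / k**2 for k, v in pdiff.items() if k >= 1),
            "MaximumProbability": p.max(),
            "SumEntropy": -sum(v * math.log2(v) for v in psum.values() if v > 0),
        }
        for k, v in feats.items():
            acc[k] = acc.get(k, 0.0) + v
    return {f"glcm_{k}": v / n_dirs for k, v in acc.items()}


def glrlm_runs_naive(levels, mask, offset):
    """Enumerate maximal runs along one direction; returns {(level, len): count}."""
    shape = levels.shape
    runs = {}
    for x, y, z in np.argwhere(mask):
        px_, py_, pz_ = x - offset[0], y - offset[1], z - offset[2]
        inside = (0 <= px_ < shape[0] and 0 <= py_ < shape[1] and 0 <= pz_ < shape[2])
        if inside and mask[px_, py_, pz_] and levels[px_, py_, pz_] == levels[x, y, z]:
            continue  # not a run start
        length = 1
        cx, cy, cz = x, y, z
        while True:
            nx, ny, nz = cx + offset[0], cy + offset[1], cz + offset[2]
            if not (0 <= nx < shape[0] and 0 <= ny < shape[1] and 0 <= nz < shape[2]):
                break
            if not mask[nx, ny, nz] or levels[nx, ny, nz] != levels[x, y, z]:
                break
            length += 1
            cx, cy, cz = nx, ny, nz
        key = (int(levels[x, y, z]), length)
        runs[key] = runs.get(key, 0) + 1
    return runs


def rl_style_features_naive(P: np.ndarray, n_voxels: int, prefix_small, prefix_large,
                            prefix_col, prefix_pct):
    """Generic run-length/size-zone feature formulas from a counts matrix."""
    ng, nj = P.shape
    nr = P.sum()
    out = {}
    out[prefix_small] = sum(P[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nj)) / nr
    out[prefix_large] = sum(P[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nj)) / nr
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    out["GrayLevelNonUniformity"] = sum(r * r for r in row) / nr
    out["GrayLevelNonUniformityNormalized"] = sum(r * r for r in row) / nr**2
    out[prefix_col] = sum(c * c for c in col) / nr
    out[prefix_col + "Normalized"] = sum(c * c for c in col) / nr**2
    out[prefix_pct] = nr / n_voxels
    p = P / nr
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(nj))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(nj))
    out["GrayLevelVariance"] = sum(((i + 1) - mu_i) ** 2 * p[i, j]
                                   for i in range(ng) for j in range(nj))
    out["_jvar"] = sum(((j + 1) - mu_j) ** 2 * p[i, j] for i in range(ng) for j in range(nj))
    out["_entropy"] = -sum(v * math.log2(v) for v in p.ravel() if v > 0)
    out["Low"] = sum(P[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nj)) / nr
    out["High"] = sum(P[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nj)) / nr
    out["SmallLow"] = sum(P[i, j] / ((i + 1) ** 2 * (j + 1) ** 2)
                          for i in range(ng) for j in range(nj)) / nr
    out["SmallHigh"] = sum(P[i, j] * (i + 1) ** 2 / (j + 1) ** 2
                           for i in range(ng) for j in range(nj)) / nr
    out["LargeLow"] = sum(P[i, j] * (j + 1) ** 2 / (i + 1) ** 2
                          for i in range(ng) for j in range(nj)) / nr
    out["LargeHigh"] = sum(P[i, j] * (i + 1) ** 2 * (j + 1) ** 2
                           for i in range(ng) for j in range(nj)) / nr
    return out


def glrlm_features_naive(levels, mask, ng, n_voxels, max_len):
    mapping = [
        ("glrlm_ShortRunEmphasis", "SRE"), ("glrlm_LongRunEmphasis", "LRE"),
    ]
    acc = None
    n_dirs = 0
    for off in DIRECTIONS_13:
        runs = glrlm_runs_naive(levels, mask, off)
        if not runs:
            continue
        P = np.zeros((ng, max_len))
        for (lv, ln), c in runs.items():
            P[lv - 1, ln - 1] += c
        f = rl_style_features_naive(P, n_voxels, "SRE", "LRE", "RLN", "RP")
        named = {
            "glrlm_ShortRunEmphasis": f["SRE"],
            "glrlm_LongRunEmphasis": f["LRE"],
            "glrlm_GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
            "glrlm_GrayLevelNonUniformityNormalized": f["GrayLevelNonUniformityNormalized"],
            "glrlm_RunLengthNonUniformity": f["RLN"],
            "glrlm_RunLengthNonUniformityNormalized": f["RLNNormalized"],
            "glrlm_RunPercentage": f["RP"],
            "glrlm_GrayLevelVariance": f["GrayLevelVariance"],
            "glrlm_RunVariance": f["_jvar"],
            "glrlm_RunEntropy": f["_entropy"],
            "glrlm_LowGrayLevelRunEmphasis": f["Low"],
            "glrlm_HighGrayLevelRunEmphasis": f["High"],
            "glrlm_ShortRunLowGrayLevelEmphasis": f["SmallLow"],
            "glrlm_ShortRunHighGrayLevelEmphasis": f["SmallHigh"],
            "glrlm_LongRunLowGrayLevelEmphasis": f["LargeLow"],
            "glrlm_LongRunHighGrayLevelEmphasis": f["LargeHigh"],
        }
        n_dirs += 1
        if acc is None:
            acc = {k: v for k, v in named.items()}
        else:
            for k, v in named.items():
                acc[k] += v
    return {k: v / n_dirs for k, v in acc.items()}


def _zones_naive(levels, mask, g):
    """26-connected zones of level g via flood fill."""
    target = (levels == g) & mask
    seen = np.zeros_like(target)
    sizes = []
    shape = target.shape
    for start in map(tuple, np.argwhere(target)):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        size = 0
        while stack:
            cx, cy, cz = stack.pop()
            size += 1
            for ox, oy, oz in itertools.product((-1, 0, 1), repeat=3):
                if ox == oy == oz == 0:
                    continue
                nb = (cx + ox, cy + oy, cz + oz)
                if (0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1]
                        and 0 <= nb[2] < shape[2] and target[nb] and not seen[nb]):
                    seen[nb] = True
                    stack.append(nb)
        sizes.append(size)
    return sizes


def glszm_features_naive(levels, mask, ng, n_voxels):
    zones = []
    for g in range(1, ng + 1):
        zones.extend((g, s) for s in _zones_naive(levels, mask, g))
    max_size = max(s for _, s in zones)
    P = np.zeros((ng, max_size))
    for g, s in zones:
        P[g - 1, s - 1] += 1
    f = rl_style_features_naive(P, n_voxels, "SAE", "LAE", "SZN", "ZP")
    return {
        "glszm_SmallAreaEmphasis": f["SAE"],
        "glszm_LargeAreaEmphasis": f["LAE"],
        "glszm_GrayLevelNonUniformity": f["GrayLevelNonUniformity"],
        "glszm_GrayLevelNonUniformityNormalized": f["GrayLevelNonUniformityNormalized"],
        "glszm_SizeZoneNonUniformity": f["SZN"],
        "glszm_SizeZoneNonUniformityNormalized": f["SZNNormalized"],
        "glszm_ZonePercentage": f["ZP"],
        "glszm_GrayLevelVariance": f["GrayLevelVariance"],
        "glszm_ZoneVariance": f["_jvar"],
        "glszm_ZoneEntropy": f["_entropy"],
        "glszm_LowGrayLevelZoneEmphasis": f["Low"],
        "glszm_HighGrayLevelZoneEmphasis": f["High"],
        "glszm_SmallAreaLowGrayLevelEmphasis": f["SmallLow"],
        "glszm_SmallAreaHighGrayLevelEmphasis": f["SmallHigh"],
        "glszm_LargeAreaLowGrayLevelEmphasis": f["LargeLow"],
        "glszm_LargeAreaHighGrayLevelEmphasis": f["LargeHigh"],
    }


def _neighbours26(shape, x, y, z):
    for ox, oy, oz in itertools.product((-1, 0, 1), repeat=3):
        if ox == oy == oz == 0:
            continue
        nb = (x + ox, y + oy, z + oz)
        if 0 <= nb[0] < shape[0] and 0 <= nb[1] < shape[1] and 0 <= nb[2] < shape[2]:
            yield nb


def gldm_features_naive(levels, mask, ng):
    shape = levels.shape
    entries = []
    for x, y, z in np.argwhere(mask):
        dep = 1
        for nb in _neighbours26(shape, x, y, z):
            if mask[nb] and levels[nb] == levels[x, y, z]:
                dep += 1
        entries.append((int(levels[x, y, z]), dep))
    nd = max(d for _, d in entries)
    P = np.zeros((ng, nd))
    for g, d in entries:
        P[g - 1, d - 1] += 1
    nz = P.sum()
    p = P / nz
    mu_i = sum((i + 1) * p[i, j] for i in range(ng) for j in range(nd))
    mu_j = sum((j + 1) * p[i, j] for i in range(ng) for j in range(nd))
    row = P.sum(axis=1)
    col = P.sum(axis=0)
    return {
        "gldm_SmallDependenceEmphasis": sum(P[i, j] / (j + 1) ** 2 for i in range(ng) for j in range(nd)) / nz,
        "gldm_LargeDependenceEmphasis": sum(P[i, j] * (j + 1) ** 2 for i in range(ng) for j in range(nd)) / nz,
        "gldm_GrayLevelNonUniformity": sum(r * r for r in row) / nz,
        "gldm_DependenceNonUniformity": sum(c * c for c in col) / nz,
        "gldm_DependenceNonUniformityNormalized": sum(c * c for c in col) / nz**2,
        "gldm_GrayLevelVariance": sum(((i + 1) - mu_i) ** 2 * p[i, j] for i in range(ng) for j in range(nd)),
        "gldm_DependenceVariance": sum(((j + 1) - mu_j) ** 2 * p[i, j] for i in range(ng) for j in range(nd)),
        "gldm_DependenceEntropy": -sum(v * math.log2(v) for v in p.ravel() if v > 0),
        "gldm_LowGrayLevelEmphasis": sum(P[i, j] / (i + 1) ** 2 for i in range(ng) for j in range(nd)) / nz,
        "gldm_HighGrayLevelEmphasis": sum(P[i, j] * (i + 1) ** 2 for i in range(ng) for j in range(nd)) / nz,
        "gldm_SmallDependenceLowGrayLevelEmphasis": sum(
            P[i, j] / ((i + 1) ** 2 * (j + 1) ** 2) for i in range(ng) for j in range(nd)) / nz,
        "gldm_SmallDependenceHighGrayLevelEmphasis": sum(
            P[i, j] * (i + 1) ** 2 / (j + 1) ** 2 for i in range(ng) for j in range(nd)) / nz,
        "gldm_LargeDependenceLowGrayLevelEmphasis": sum(
            P[i, j] * (j + 1) ** 2 / (i + 1) ** 2 for i in range(ng) for j in range(nd)) / nz,
        "gldm_LargeDependenceHighGrayLevelEmphasis": sum(
            P[i, j] * (i + 1) ** 2 * (j + 1) ** 2 for i in range(ng) for j in range(nd)) / nz,
    }


def ngtdm_features_naive(levels, mask, ng, cap=1e6):
    shape = levels.shape
    s = np.zeros(ng)
    n_i = np.zeros(ng)
    n_valid = 0
    for x, y, z in np.argwhere(mask):
        vals = [levels[nb] for nb in _neighbours26(shape, x, y, z) if mask[nb]]
        if not vals:
            continue
        n_valid += 1
        g = int(levels[x, y, z])
        s[g - 1] += abs(g - sum(vals) / len(vals))
        n_i[g - 1] += 1
    p = n_i / n_valid if n_valid else n_i
    present = [i for i in range(ng) if p[i] > 0]
    ngp = len(present)
    denom = sum(p[i] * s[i] for i in present)
    coarse = min(1.0 / denom, cap) if denom > 0 else cap
    if ngp > 1 and n_valid:
        contrast = (sum(p[i] * p[j] * (i - j) ** 2 for i in present for j in present)
                    / (ngp * (ngp - 1))) * (sum(s) / n_valid)
        busy_den = sum(abs((i + 1) * p[i] - (j + 1) * p[j]) for i in present for j in present)
        busy = denom / busy_den if busy_den > 0 else 0.0
        cplx = sum(abs(i - j) * (p[i] * s[i] + p[j] * s[j]) / (p[i] + p[j])
                   for i in present for j in present) / n_valid
        strength = (sum((p[i] + p[j]) * (i - j) ** 2 for i in present for j in present)
                    / sum(s)) if sum(s) > 0 else 0.0
    else:
        contrast = busy = cplx = strength = 0.0
    return {
        "ngtdm_Coarseness": coarse,
        "ngtdm_Contrast": contrast,
        "ngtdm_Complexity": cplx,
        "ngtdm_Busyness": busy,
        "ngtdm_Strength": strength,
    }


# ---------------------------------------------------------------------------
# statistics

def icc_2_1_mean_squares(y1, y2):
    """ICC(2,1) from the explicit two-way ANOVA mean squares."""
    y1 = np.asarray(y1, float)
    y2 = np.asarray(y2, float)
    n = len(y1)
    k = 2
    data = np.stack([y1, y2], axis=1)
    grand = data.mean()
    msr = k * sum((data[i].mean() - grand) ** 2 for i in range(n)) / (n - 1)
    msc = n * sum((data[:, j].mean() - grand) ** 2 for j in range(k)) / (k - 1)
    sse = sum((data[i, j] - data[i].mean() - data[:, j].mean() + grand) ** 2
              for i in range(n) for j in range(k))
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def auc_pair_count(scores, labels):
    """AUC by exhaustive pair counting with half-credit ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else (0.5 if a == b else 0.0)
    return total / (len(pos) * len(neg))


def pauc_dense_grid(scores, labels, max_fpr=0.05, n_per_segment=2000):
    """Numerical integration of the ROC polyline restricted to
    FPR <= max_fpr: every segment is densely sampled with scalar
    arithmetic and summed with the trapezoid rule, clipping the segment
    that crosses the boundary."""
    scores = list(map(float, scores))
    y = list(map(bool, labels))
    pairs = sorted(zip(scores, y), key=lambda p: -p[0])
    n_pos = sum(y)
    n_neg = len(y) - n_pos
    verts = [(0.0, 0.0)]
    tp = fp = 0
    i = 0
    while i < len(pairs):
        j = i
        while j < len(pairs) and pairs[j][0] == pairs[i][0]:
            tp += pairs[j][1]
            fp += not pairs[j][1]
            j += 1
        verts.append((fp / n_neg, tp / n_pos))
        i = j
    area = 0.0
    for (f1, t1), (f2, t2) in zip(verts, verts[1:]):
        if f1 >= max_fpr:
            break
        if f2 > max_fpr:  # clip the crossing segment
            t2 = t1 + (t2 - t1) * (max_fpr - f1) / (f2 - f1)
            f2 = max_fpr
        if f2 == f1:
            continue
        # dense sampling of the (linear) segment
        prev_f, prev_t = f1, t1
        for k in range(1, n_per_segment + 1):
            fk = f1 + (f2 - f1) * k / n_per_segment
            tk = t1 + (t2 - t1) * k / n_per_segment
            area += (fk - prev_f) * (tk + prev_t) / 2.0
            prev_f, prev_t = fk, tk
    return area


def net_benefit_confusion(prob, labels, t):
    """Direct confusion-matrix net benefit at one threshold."""
    tp = fp = 0
    n = len(labels)
    for p, l in zip(prob, labels):
        if p >= t:
            if l:
                tp += 1
            else:
                fp += 1
    return tp / n - (fp / n) * (t / (1 - t))
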