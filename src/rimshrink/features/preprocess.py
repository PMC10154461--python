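"""Preprocessing before feature extraction: windowing, nearest-neighbour
resampling to an isotropic grid, and fixed-bin-width grey-level
discretization.

The resampled grid spans the same physical extent as the input, with
ceil(extent_mm / target_spacing) voxels per axis.  Each output voxel takes
the value of the input voxel whose mm interval contains the output voxel
centre (equivalently the nearest input voxel centre; exact half-way ties
resolve to the containing, i.e. larger-index, voxel).

Discretization is min-anchored: level(x) = floor((x - min_ROI) / bin_width) + 1,
so the ROI minimum always maps to level 1 and levels are translation
invariant under global HU shifts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from ..errors import ConfigError, EmptyROIError
from ..io import CTVolume, LesionMask


@dataclass(frozen=True)
class PreprocessConfig:
    """Extraction preprocessing parameters.

    target_spacing: isotropic resampling spacing in mm (default 3).
    bin_width: grey-level bin width in HU (default 25).
    window: optional (level, width) HU clamp applied before resampling;
        None disables windowing.
    """

    target_spacing: tuple[float, float, float] = (3.0, 3.0, 3.0)
    bin_width: float = 25.0
    window: Optional[tuple[float, float]] = (40.0, 400.0)

    def __post_init__(self):
        if any(s <= 0 for s in self.target_spacing):
            raise ConfigError(f"target spacing must be positive, got {self.target_spacing}")
        if self.bin_width <= 0:
            raise ConfigError(f"bin width must be positive, got {self.bin_width}")
        if self.window is not None and self.window[1] <= 0:
            raise ConfigError(f"window width must be positive, got {self.window}")


def apply_window(volume: CTVolume, level: float, width: float) -> CTVolume:
    """Clamp attenuation to [level - width/2, level + width/2]."""
    if width <= 0:
        raise ConfigError(f"window width must be positive, got {width}")
    lo, hi = level - width / 2.0, level + width / 2.0
    return CTVolume(values=np.clip(volume.values, lo, hi), spacing=volume.spacing)


def _nn_index_map(n_in: int, d_in: float, d_out: float, n_out: int) -> np.ndarray:
    centres = (np.arange(n_out) + 0.5) * d_out
    idx = np.floor(centres / d_in).astype(np.intp)
    return np.clip(idx, 0, n_in - 1)


def resample_nn(volume: CTVolume, mask: LesionMask,
                target_spacing=(3.0, 3.0, 3.0)) -> tuple[CTVolume, LesionMask]:
    """Nearest-neighbour resample of volume and mask to target_spacing.

    Both grids use the same index map, so the mask stays binary and aligned.
    """
    if mask.shape != volume.shape:
        raise ConfigError("volume and mask must share a grid")
    shape = volume.shape
    spacing = volume.spacing
    target = tuple(float(t) for t in target_spacing)
    n_out = tuple(
        int(np.ceil(shape[a] * spacing[a] / target[a])) for a in range(3)
    )
    maps = [_nn_index_map(shape[a], spacing[a], target[a], n_out[a]) for a in range(3)]
    out_vals = volume.values[np.ix_(*maps)]
    out_mask = mask.labels[np.ix_(*maps)]
    return (CTVolume(values=out_vals, spacing=target), LesionMask(labels=out_mask))


@dataclass
class GreyLevelROI:
    """Discretized ROI: integer levels 1..Ng at the ROI voxels.

    level_grid holds the level at ROI voxels and 0 elsewhere, cropped to
    the ROI bounding box with a 1-voxel zero pad (texture code relies on
    the pad).  raw_values are the (windowed, resampled) HU values of the
    ROI voxels in C order of the original grid.
    """

    level_grid: np.ndarray  # intp, bbox + 1 pad
    mask_grid: np.ndarray  # bool, same shape
    ng: int
    raw_values: np.ndarray
    spacing: tuple[float, float, float]
    bin_width: float

    @property
    def num_voxels(self) -> int:
        return int(self.mask_grid.sum())

    @property
    def levels(self) -> np.ndarray:
        """Levels of the ROI voxels (1..Ng)."""
        return self.level_grid[self.mask_grid]


def discretize(volume: CTVolume, mask: LesionMask, bin_width: float = 25.0) -> GreyLevelROI:
    """Fixed-bin-width, min-anchored discretization over the ROI."""
    if bin_width <= 0:
        raise ConfigError(f"bin width must be positive, got {bin_width}")
    fg = mask.labels.astype(bool)
    if not fg.any():
        raise EmptyROIError("cannot discretize an empty ROI")
    vals = volume.values[fg]
    levels_flat = np.floor((vals - vals.min()) / bin_width).astype(np.intp) + 1
    ng = int(levels_flat.max())
    # crop to bounding box with one-voxel zero pad
    idx = np.nonzero(fg)
    lo = [int(i.min()) for i in idx]
    hi = [int(i.max()) + 1 for i in idx]
    box = tuple(slice(lo[a], hi[a]) for a in range(3))
    mask_box = np.pad(fg[box], 1)
    grid = np.zeros_like(mask_box, dtype=np.intp)
    full_grid = np.zeros(fg.shape, dtype=np.intp)
    full_grid[fg] = levels_flat
    grid[1:-1, 1:-1, 1:-1] = full_grid[box]
    return GreyLevelROI(
        level_grid=grid, mask_grid=mask_box, ng=ng, raw_values=vals,
        spacing=volume.spacing, bin_width=float(bin_width),
    )
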