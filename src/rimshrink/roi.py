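"""The four ROI variants: MAX, MAX_E, ALL, ALL_E.

MAX is the maximum-area single slice of the lesion mask, ALL the full
volume.  The eroded variants MAX_E / ALL_E shrink the mask inward by a
millimetre-calibrated radius (default 3 mm) to strip the partial-volume rim:
a voxel is retained iff its Euclidean distance (in mm, using the voxel
spacing) to the nearest background voxel centre exceeds the radius.  MAX_E
erodes within the slice plane only; ALL_E erodes in full 3D.

Erosion runs at native resolution, before any feature-extraction
resampling.  Masks touching the grid edge see no background beyond the
edge, so the edge itself does not erode them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConfigError, EmptyROIError
from .io import LesionMask

ROI_METHODS = ("MAX", "MAX_E", "ALL", "ALL_E")


def largest_area_slice(mask: LesionMask, spacing) -> int:
    """z index of the slice with the largest foreground area in mm^2.

    Area per slice is voxel count x dx x dy, so with uniform in-plane
    spacing the argmax is the argmax of the count.  Ties break to the
    smallest z.
    """
    labels = mask.labels
    counts = labels.sum(axis=(0, 1))
    if counts.sum() == 0:
        raise EmptyROIError("cannot select maximum-area slice of an empty mask")
    return int(np.argmax(counts))  # argmax returns the first maximum


def erode_mm(mask: LesionMask, spacing, radius_mm: float,
             mode: str = "full_3d", case_id=None) -> LesionMask:
    """Erode a binary mask by a physical radius in mm.

    mode "in_plane_2d": distances computed within each z slice using
    (dx, dy); mode "full_3d": 3D distances using (dx, dy, dz).  Radius 0 is
    the identity.  Implemented by thresholding the exact Euclidean distance
    transform of the foreground.
    """
    if radius_mm < 0:
        raise ConfigError(f"erosion radius must be >= 0, got {radius_mm}")
    if mode not in ("in_plane_2d", "full_3d", "box_3d"):
        raise ConfigError(f"unknown erosion mode {mode!r}")
    labels = mask.labels.astype(bool)
    if radius_mm == 0:
        return LesionMask(labels=labels.copy())
    if mode == "box_3d":
        # per-axis (separable box) shrinkage: r mm independently along x, y, z
        widths = [int(np.floor(radius_mm / float(s))) for s in spacing]
        if max(widths) == 0:
            return LesionMask(labels=labels.copy())
        structure = np.ones([2 * w + 1 for w in widths], dtype=bool)
        out = ndimage.binary_erosion(labels, structure=structure, border_value=1)
        if not out.any():
            raise EmptyROIError(
                f"box erosion by {radius_mm} mm emptied the mask",
                case_id=case_id, method=mode)
        return LesionMask(labels=out)
    if not labels.any():
        raise EmptyROIError("cannot erode an empty mask", case_id=case_id, method=mode)
    dx, dy, dz = (float(s) for s in spacing)
    # Crop to the foreground bounding box expanded by ceil(radius/spacing)+1:
    # every background voxel within `radius_mm` of any foreground voxel lies
    # inside the crop, so thresholding the cropped EDT at radius_mm is exact.
    idx = np.nonzero(labels)
    margin = [int(np.ceil(radius_mm / s)) + 1 for s in (dx, dy, dz)]
    lo = [max(0, int(i.min()) - m) for i, m in zip(idx, margin)]
    hi = [min(n, int(i.max()) + 1 + m) for i, n, m in zip(idx, labels.shape, margin)]
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = labels[box]
    if mode == "in_plane_2d":
        dist = np.zeros(sub.shape, dtype=np.float64)
        for z in range(sub.shape[2]):
            sl = sub[:, :, z]
            if sl.any():
                dist[:, :, z] = ndimage.distance_transform_edt(sl, sampling=(dx, dy))
    else:
        dist = ndimage.distance_transform_edt(sub, sampling=(dx, dy, dz))
    out = np.zeros_like(labels)
    out[box] = dist > radius_mm
    if not out.any():
        raise EmptyROIError(
            f"erosion by {radius_mm} mm ({mode}) emptied the mask",
            case_id=case_id, method=mode,
        )
    return LesionMask(labels=out)


@dataclass
class ROISet:
    """The four derived masks for one case."""

    masks: dict[str, LesionMask] = field(default_factory=dict)
    max_slice_index: int = 0
    erosion_radius_mm: float = 3.0

    def __getitem__(self, method: str) -> LesionMask:
        return self.masks[method]

    def items(self):
        return self.masks.items()


def derive_rois(mask: LesionMask, spacing, radius_mm: float = 3.0,
                case_id=None) -> ROISet:
    """Derive {MAX, MAX_E, ALL, ALL_E} from a full-volume lesion mask.

    ALL is the input mask; MAX restricts it to the maximum-area slice;
    MAX_E applies in-plane 2D erosion to MAX; ALL_E applies full-3D erosion
    to ALL.  Raises EmptyROIError naming the failing method if any derived
    ROI is empty.
    """
    mask.require_nonempty(case_id=case_id, method="ALL")
    z = largest_area_slice(mask, spacing)
    max_labels = np.zeros_like(mask.labels)
    max_labels[:, :, z] = mask.labels[:, :, z]
    max_mask = LesionMask(labels=max_labels)
    try:
        max_e = erode_mm(max_mask, spacing, radius_mm, mode="in_plane_2d", case_id=case_id)
    except EmptyROIError:
        raise EmptyROIError(
            f"MAX_E empty after {radius_mm} mm in-plane erosion",
            case_id=case_id, method="MAX_E",
        )
    try:
        all_e = erode_mm(mask, spacing, radius_mm, mode="full_3d", case_id=case_id)
    except EmptyROIError:
        raise EmptyROIError(
            f"ALL_E empty after {radius_mm} mm 3D erosion",
            case_id=case_id, method="ALL_E",
        )
    return ROISet(
        masks={"MAX": max_mask, "MAX_E": max_e, "ALL": LesionMask(labels=mask.labels.copy()),
               "ALL_E": all_e},
        max_slice_index=z,
        erosion_radius_mm=radius_mm,
    )
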