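"""Volumes, masks, cases, manifests and feature tables.

CT volumes and lesion masks travel as NIfTI (.nii/.nii.gz); manifests and
feature tables as UTF-8 CSV with '.' decimal separator.  Axis order is
(x, y, z) with z the slice axis; voxel spacing in millimetres comes from the
NIfTI header pixdim.  Orientation matrices beyond spacing are ignored (the
method depends only on spacing); a warning is logged when the affine carries
rotation/shear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import (
    EmptyROIError,
    GeometryError,
    HeaderError,
    IntegrityError,
    VocabularyError,
)

logger = logging.getLogger(__name__)

LABELS = ("adenoma", "non_adenoma")
POSITIVE_LABEL = "adenoma"  # the diagnostic target class


@dataclass(frozen=True)
class CTVolume:
    """A 3D attenuation grid in Hounsfield units with mm voxel spacing."""

    values: np.ndarray  # float array, shape (nx, ny, nz)
    spacing: tuple[float, float, float]  # (dx, dy, dz) in mm

    def __post_init__(self):
        values = np.asarray(self.values, dtype=np.float64)
        if values.ndim != 3 or values.size == 0:
            raise GeometryError("volume must be a non-empty 3D grid")
        if not np.all(np.isfinite(values)):
            raise HeaderError("volume contains non-finite attenuation values")
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) != 3 or not all(np.isfinite(s) and s > 0 for s in spacing):
            raise HeaderError(f"spacing must be three positive finite mm values, got {spacing}")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        dx, dy, dz = self.spacing
        return dx * dy * dz


@dataclass(frozen=True)
class LesionMask:
    """Binary foreground mask aligned to a CTVolume grid (1 = lesion)."""

    labels: np.ndarray

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3 or labels.size == 0:
            raise GeometryError("mask must be a non-empty 3D grid")
        binary = (labels != 0).astype(np.uint8)
        object.__setattr__(self, "labels", binary)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def num_foreground(self) -> int:
        return int(self.labels.sum())

    def require_nonempty(self, case_id=None, method=None) -> "LesionMask":
        if self.num_foreground == 0:
            raise EmptyROIError("mask has no foreground voxels", case_id=case_id, method=method)
        return self


@dataclass
class LesionCase:
    """One lesion: volume, rater-1 mask, optional rater-2 mask, class label."""

    case_id: str
    volume: CTVolume
    mask_rater1: LesionMask
    mask_rater2: Optional[LesionMask] = None
    label: str = "adenoma"
    institution: str = "A"
    ground_truth: Optional[dict] = None  # phantom-only metadata

    def __post_init__(self):
        if self.label not in LABELS:
            raise VocabularyError(
                f"label {self.label!r} not in accepted vocabulary {LABELS}"
            )
        for name, mask in (("mask_rater1", self.mask_rater1), ("mask_rater2", self.mask_rater2)):
            if mask is not None and mask.shape != self.volume.shape:
                raise GeometryError(
                    f"{name} shape {mask.shape} does not match volume shape {self.volume.shape}"
                )


def _check_affine(img, path):
    affine = img.affine
    if affine is not None:
        rot = affine[:3, :3]
        off_diag = rot - np.diag(np.diag(rot))
        if np.any(np.abs(off_diag) > 1e-6):
            logger.warning("ignoring non-diagonal orientation in %s (only spacing is used)", path)


def read_volume(path) -> CTVolume:
    """Read a NIfTI volume; spacing from the header pixdim."""
    img = nib.load(str(path))
    _check_affine(img, path)
    zooms = img.header.get_zooms()[:3]
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise GeometryError(f"{path}: expected a 3D volume, got ndim={data.ndim}")
    if not all(np.isfinite(z) and z > 0 for z in zooms):
        raise HeaderError(f"{path}: non-positive voxel spacing {zooms} in header")
    return CTVolume(values=np.asarray(data, dtype=np.float64), spacing=tuple(float(z) for z in zooms))


def write_volume(volume: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI with spacing in the header."""
    affine = np.diag(list(volume.spacing) + [1.0])
    img = nib.Nifti1Image(volume.values.astype(np.float32), affine)
    img.header.set_zooms(volume.spacing)
    nib.save(img, str(path))


def write_mask(mask: LesionMask, spacing, path) -> None:
    affine = np.diag(list(spacing) + [1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), affine)
    img.header.set_zooms(tuple(spacing))
    nib.save(img, str(path))


def read_case(volume_path, mask_path, label, case_id=None, mask2_path=None,
              institution="A") -> LesionCase:
    """Load a volume + mask pair from NIfTI; binarize the mask (nonzero -> 1)."""
    volume = read_volume(volume_path)
    mask_img = nib.load(str(mask_path))
    mask_data = np.asanyarray(mask_img.dataobj)
    if mask_data.shape != volume.shape:
        raise GeometryError(
            f"mask shape {mask_data.shape} does not match volume shape {volume.shape}"
        )
    n_labels = np.unique(mask_data)
    if len(n_labels) > 2 or (len(n_labels) == 2 and 1 not in n_labels):
        logger.info("mask %s has labels %s; binarizing nonzero -> 1", mask_path, n_labels)
    mask = LesionMask(labels=mask_data).require_nonempty(case_id=case_id)
    mask2 = None
    if mask2_path is not None and str(mask2_path):
        mask2_data = np.asanyarray(nib.load(str(mask2_path)).dataobj)
        if mask2_data.shape != volume.shape:
            raise GeometryError(
                f"rater-2 mask shape {mask2_data.shape} does not match volume shape {volume.shape}"
            )
        mask2 = LesionMask(labels=mask2_data).require_nonempty(case_id=case_id)
    if case_id is None:
        case_id = Path(volume_path).name.split(".")[0]
    return LesionCase(case_id=str(case_id), volume=volume, mask_rater1=mask,
                      mask_rater2=mask2, label=label, institution=institution)


def load_manifest(path) -> list[LesionCase]:
    """Load cases from a manifest CSV.

    Required columns: case_id, volume, mask_rater1, label; optional:
    mask_rater2, institution.  Relative paths resolve against the manifest's
    directory.  Cases are returned in manifest order.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    required = {"case_id", "volume", "mask_rater1", "label"}
    missing = required - set(df.columns)
    if missing:
        raise IntegrityError(f"manifest missing columns: {sorted(missing)}")
    if df["case_id"].duplicated().any():
        dupes = df.loc[df["case_id"].duplicated(), "case_id"].tolist()
        raise IntegrityError(f"duplicated case_id values in manifest: {dupes}")
    bad = sorted(set(df["label"]) - set(LABELS))
    if bad:
        raise VocabularyError(f"unknown labels {bad}; accepted: {list(LABELS)}")
    base = path.parent

    def _resolve(p):
        if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
            return None
        p = Path(p)
        return p if p.is_absolute() else base / p

    cases = []
    for row in df.itertuples(index=False):
        mask2 = getattr(row, "mask_rater2", None)
        if isinstance(mask2, float) and np.isnan(mask2):
            mask2 = None
        cases.append(read_case(
            _resolve(row.volume), _resolve(row.mask_rater1), row.label,
            case_id=row.case_id, mask2_path=_resolve(mask2) if mask2 else None,
            institution=getattr(row, "institution", "A") or "A",
        ))
    return cases


# ---------------------------------------------------------------------------
# Feature tables

@dataclass
class FeatureTable:
    """Cases x features, keyed by (case_id, roi_method).

    Stored as a DataFrame with index columns case_id / roi_method and one
    column per feature; all values finite reals.
    """

    data: pd.DataFrame = field(default_factory=pd.DataFrame)

    KEY_COLS = ("case_id", "roi_method")

    def __post_init__(self):
        df = self.data
        if df.index.names != list(self.KEY_COLS):
            if all(c in df.columns for c in self.KEY_COLS):
                df = df.set_index(list(self.KEY_COLS))
            elif len(df) == 0:
                df = pd.DataFrame(
                    index=pd.MultiIndex.from_arrays([[], []], names=self.KEY_COLS)
                )
            else:
                raise IntegrityError("feature table requires case_id and roi_method keys")
        if df.index.duplicated().any():
            dupes = df.index[df.index.duplicated()].tolist()
            raise IntegrityError(f"duplicate (case_id, roi_method) rows: {dupes}")
        if len(df) and not np.all(np.isfinite(df.to_numpy(dtype=float))):
            bad = [(idx, col) for idx, col in zip(*np.where(~np.isfinite(df.to_numpy(dtype=float))))]
            raise IntegrityError(f"non-finite feature values at (row, column) positions {bad[:5]}")
        self.data = df

    @property
    def feature_names(self) -> list[str]:
        return list(self.data.columns)

    def rows_for_method(self, roi_method: str) -> pd.DataFrame:
        """Feature matrix for one ROI method, indexed by case_id."""
        sel = self.data.xs(roi_method, level="roi_method")
        return sel

    def __len__(self):
        return len(self.data)


def write_feature_table(table: FeatureTable, path) -> None:
    """CSV with header; values at full float precision (round-trip safe)."""
    table.data.to_csv(path, float_format="%.17g")


def read_feature_table(path) -> FeatureTable:
    df = pd.read_csv(path, dtype={"case_id": str, "roi_method": str})
    required = set(FeatureTable.KEY_COLS)
    if not required <= set(df.columns):
        raise IntegrityError(f"feature table CSV missing key columns {sorted(required)}")
    feat_cols = [c for c in df.columns if c not in required]
    if df[feat_cols].isna().any().any():
        na = df[feat_cols].isna()
        row, col = np.argwhere(na.to_numpy())[0]
        raise IntegrityError(
            f"missing cell at row {df['case_id'].iloc[row]!r}, column {feat_cols[col]!r}"
        )
    return FeatureTable(data=df)


def write_manifest(rows: Sequence[dict], path) -> None:
    pd.DataFrame(rows).to_csv(path, index=False)
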