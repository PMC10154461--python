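"""Synthetic CT lesion phantoms with partial-volume rim contamination.

Each phantom is an axis-aligned ellipsoidal lesion on a uniform background,
voxelized on an anisotropic grid (default 1 x 1 x 3.75 mm, echoing clinical
reconstructed slice thicknesses).  The lesion interior carries a stationary
Gaussian random field (squared-exponential correlation, class-dependent
length) around a per-case mean drawn near the class attenuation; the whole
volume is then blurred with an isotropic-in-mm Gaussian point-spread
function, which mixes lesion and background attenuation in the rim voxels
— the partial-volume mechanism the eroded ROIs are designed to strip —
and finally white measurement noise is added.

The ground-truth mask is the pre-blur ellipsoid.  A second rater is
simulated by a smooth random boundary perturbation of bounded normal
displacement, mirroring an inter-rater re-segmentation without an
interactive tool.

Randomness uses numpy's PCG64 generator throughout; equal seeds give
bit-identical cohorts (the algorithm name is recorded in config metadata).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .errors import ConfigError, EmptyROIError, GeometryError
from .io import CTVolume, LesionCase, LesionMask, write_manifest, write_mask, write_volume

RNG_ALGORITHM = "PCG64"


@dataclass(frozen=True)
class LesionClassParams:
    """Per-class lesion parameters.

    mean_hu: class mean attenuation of the lesion tissue.
    between_case_sd_hu: sd of the per-case lesion mean around mean_hu
        (patient-to-patient attenuation spread).
    texture_sd_hu: pointwise sd of the intra-lesion texture field.
    corr_length_mm: correlation length of the texture field.
    axis_range_mm: (lo, hi) range for each ellipsoid axis diameter; lo must
        respect the 10-mm minimum lesion diameter inclusion floor.
    """

    mean_hu: float
    between_case_sd_hu: float
    texture_sd_hu: float
    corr_length_mm: float
    axis_range_mm: tuple[float, float]
    # through-plane (z) diameter range; None reuses axis_range_mm.  Defaults
    # sit toward the upper range so the polar cap slices — whose partial
    # volume a 3-mm erosion cannot reach under 3.75-5 mm slices — stay small.
    z_axis_range_mm: tuple[float, float] | None = None

    @property
    def z_range(self) -> tuple[float, float]:
        return self.z_axis_range_mm if self.z_axis_range_mm is not None else self.axis_range_mm


@dataclass(frozen=True)
class PhantomConfig:
    shape: tuple[int, int, int] = (64, 64, 20)
    spacing: tuple[float, float, float] = (1.0, 1.0, 3.75)
    background_mean: float = -30.0
    # The tissue abutting an adrenal lesion is bimodal across patients:
    # retroperitoneal fat or a solid organ (liver/kidney/spleen/crus).  The
    # per-case surrounding attenuation is drawn from these (value, weight)
    # modes plus a jitter; this is the "volume confounding" the eroded ROIs
    # strip.  Set to () to use background_mean for every case.
    background_modes_hu: tuple[tuple[float, float], ...] = ((-90.0, 0.4), (45.0, 0.6))
    background_between_case_sd: float = 12.0
    adenoma: LesionClassParams = field(default_factory=lambda: LesionClassParams(
        mean_hu=20.2, between_case_sd_hu=9.0, texture_sd_hu=10.0,
        corr_length_mm=3.0, axis_range_mm=(20.0, 42.0), z_axis_range_mm=(30.0, 46.0)))
    non_adenoma: LesionClassParams = field(default_factory=lambda: LesionClassParams(
        mean_hu=37.4, between_case_sd_hu=9.0, texture_sd_hu=14.0,
        corr_length_mm=6.0, axis_range_mm=(22.0, 45.0), z_axis_range_mm=(32.0, 50.0)))
    psf_sigma_mm: float = 2.0
    noise_sd: float = 10.0
    rater_amplitude_mm: float = 1.5
    # Reconstructed slice thickness drawn per case (clinical cohorts mix
    # 3.75 and 5.00 mm about evenly); set a single value to pin it.
    slice_thickness_choices: tuple[float, ...] = (3.75, 5.0)
    rng_algorithm: str = RNG_ALGORITHM

    MIN_DIAMETER_MM = 10.0  # inclusion floor: lesions below 1 cm are excluded

    def __post_init__(self):
        if any(s <= 0 for s in self.spacing) or any(n < 1 for n in self.shape):
            raise ConfigError("grid shape and spacing must be positive")
        if self.psf_sigma_mm < 0 or self.noise_sd < 0 or self.rater_amplitude_mm < 0:
            raise ConfigError("psf sigma, noise sd and rater amplitude must be >= 0")
        if self.background_between_case_sd < 0:
            raise ConfigError("background between-case sd must be >= 0")
        if self.background_modes_hu:
            weights = [w for _, w in self.background_modes_hu]
            if any(w <= 0 for w in weights) or abs(sum(weights) - 1.0) > 1e-9:
                raise ConfigError("background mode weights must be positive and sum to 1")
        if not self.slice_thickness_choices or any(
                t <= 0 for t in self.slice_thickness_choices):
            raise ConfigError("slice thickness choices must be positive")
        for name in ("adenoma", "non_adenoma"):
            p = getattr(self, name)
            lo, hi = p.axis_range_mm
            if lo < self.MIN_DIAMETER_MM:
                raise ConfigError(
                    f"{name}: minimum axis diameter {lo} mm below the "
                    f"{self.MIN_DIAMETER_MM} mm inclusion floor")
            zlo, zhi = p.z_range
            if (hi < lo or zhi < zlo or zlo < self.MIN_DIAMETER_MM
                    or p.texture_sd_hu < 0 or p.between_case_sd_hu < 0
                    or p.corr_length_mm < 0):
                raise ConfigError(f"{name}: invalid lesion parameters")

    def params_for(self, class_label: str) -> LesionClassParams:
        if class_label == "adenoma":
            return self.adenoma
        if class_label == "non_adenoma":
            return self.non_adenoma
        raise ConfigError(f"unknown class label {class_label!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def _grf(rng: np.random.Generator, shape, corr_length_mm, spacing) -> np.ndarray:
    """Unit-variance Gaussian random field with squared-exponential
    correlation (white noise for zero length).

    corr_length_mm may be a scalar or a per-axis triple.
    """
    white = rng.standard_normal(shape)
    corr = np.broadcast_to(np.asarray(corr_length_mm, dtype=np.float64), (3,))
    if np.all(corr <= 0):
        return white
    sigma_vox = [c / s for c, s in zip(corr, spacing)]
    smooth = ndimage.gaussian_filter(white, sigma=sigma_vox, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else np.zeros(shape)


def generate_case(config: PhantomConfig, class_label: str, seed,
                  case_id: str | None = None) -> LesionCase:
    """Generate one phantom case (deterministic in (config, seed)).

    The returned case carries ground truth: true per-case lesion mean HU,
    the ellipsoid axis diameters (mm) and centre (mm).
    """
    rng = np.random.default_rng(seed)
    params = config.params_for(class_label)
    shape = config.shape
    spacing = np.asarray(config.spacing, dtype=np.float64)
    dz = float(config.slice_thickness_choices[
        rng.integers(0, len(config.slice_thickness_choices))])
    spacing = np.array([spacing[0], spacing[1], dz])
    extent = np.asarray(shape) * spacing

    lo, hi = params.axis_range_mm
    zlo, zhi = params.z_range
    diameters = np.array([rng.uniform(lo, hi), rng.uniform(lo, hi),
                          rng.uniform(zlo, zhi)])
    if np.any(diameters + 2.0 * config.psf_sigma_mm > extent):
        raise GeometryError(
            f"lesion diameters {diameters} mm do not fit grid extent {extent} mm")
    # centre near the grid middle with a sub-voxel jitter to avoid grid
    # alignment artifacts
    centre = extent / 2.0 + rng.uniform(-1.0, 1.0, size=3) * spacing / 2.0

    axes_coords = [
        ((np.arange(shape[a]) + 0.5) * spacing[a] - centre[a]) / (diameters[a] / 2.0)
        for a in range(3)
    ]
    xx = axes_coords[0][:, None, None]
    yy = axes_coords[1][None, :, None]
    zz = axes_coords[2][None, None, :]
    ellipsoid = (xx**2 + yy**2 + zz**2) <= 1.0
    if not ellipsoid.any():
        raise GeometryError("ellipsoid voxelized to an empty mask")

    case_mean = params.mean_hu + rng.normal(0.0, params.between_case_sd_hu)
    if config.background_modes_hu:
        modes = np.asarray([m for m, _ in config.background_modes_hu])
        weights = np.asarray([w for _, w in config.background_modes_hu])
        base_bg = float(modes[rng.choice(len(modes), p=weights)])
    else:
        base_bg = config.background_mean
    case_background = base_bg + rng.normal(0.0, config.background_between_case_sd)
    texture = _grf(rng, shape, params.corr_length_mm, spacing)
    volume = np.full(shape, case_background, dtype=np.float64)
    volume[ellipsoid] = case_mean + params.texture_sd_hu * texture[ellipsoid]

    if config.psf_sigma_mm > 0:
        volume = ndimage.gaussian_filter(
            volume, sigma=[config.psf_sigma_mm / s for s in spacing], mode="nearest")
    if config.noise_sd > 0:
        volume = volume + rng.normal(0.0, config.noise_sd, size=shape)

    mask1 = LesionMask(labels=ellipsoid)
    rater2_seed = int(rng.integers(0, 2**31 - 1))
    if config.rater_amplitude_mm > 0:
        mask2 = perturb_mask(mask1, tuple(spacing), config.rater_amplitude_mm, rater2_seed)
    else:
        mask2 = LesionMask(labels=ellipsoid.copy())

    if case_id is None:
        tag = seed if isinstance(seed, (int, np.integer)) else "case"
        case_id = f"{class_label}_{tag}"
    return LesionCase(
        case_id=str(case_id),
        volume=CTVolume(values=volume, spacing=tuple(spacing)),
        mask_rater1=mask1,
        mask_rater2=mask2,
        label=class_label,
        institution="phantom",
        ground_truth={
            "true_mean_hu": float(case_mean),
            "true_background_hu": float(case_background),
            "diameters_mm": tuple(float(d) for d in diameters),
            "centre_mm": tuple(float(c) for c in centre),
            "rng_algorithm": config.rng_algorithm,
        },
    )


@dataclass
class PhantomCohort:
    cases: list[LesionCase]
    config: PhantomConfig
    master_seed: int

    def __iter__(self):
        return iter(self.cases)

    def __len__(self):
        return len(self.cases)

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.cases]


def generate_cohort(config: PhantomConfig, n_per_class: int, seed: int) -> PhantomCohort:
    """Generate a balanced two-class cohort, reproducible from the master seed."""
    if n_per_class < 1:
        raise ConfigError("n_per_class must be >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2 * n_per_class)
    cases = []
    k = 0
    for class_label in ("adenoma", "non_adenoma"):
        for i in range(n_per_class):
            cases.append(generate_case(
                config, class_label, children[k], case_id=f"{class_label}_{i:03d}"))
            k += 1
    return PhantomCohort(cases=cases, config=config, master_seed=int(seed))


def perturb_mask(mask: LesionMask, spacing, amplitude_mm: float, seed) -> LesionMask:
    """Displace the mask boundary by a smooth random field.

    The signed distance to the boundary is shifted by a smooth field whose
    maximum magnitude is amplitude_mm, so every voxel farther than
    amplitude_mm (voxel-centre distance) from the boundary keeps its label;
    amplitude 0 is the identity.
    """
    if amplitude_mm < 0:
        raise ConfigError("perturbation amplitude must be >= 0")
    labels = mask.labels.astype(bool)
    if amplitude_mm == 0:
        return LesionMask(labels=labels.copy())
    if not labels.any():
        raise EmptyROIError("cannot perturb an empty mask")
    spacing = tuple(float(s) for s in spacing)
    # Work on the foreground bounding box expanded past the displacement
    # reach: voxels farther than amplitude_mm from the boundary are
    # unchanged by construction, so the crop loses nothing.
    idx = np.nonzero(labels)
    margin = [int(np.ceil(amplitude_mm / s)) + 2 for s in spacing]
    lo = [max(0, int(i.min()) - m) for i, m in zip(idx, margin)]
    hi = [min(n, int(i.max()) + 1 + m) for i, n, m in zip(idx, labels.shape, margin)]
    box = tuple(slice(l, h) for l, h in zip(lo, hi))
    sub = labels[box]
    inside = ndimage.distance_transform_edt(sub, sampling=spacing)
    outside = ndimage.distance_transform_edt(~sub, sampling=spacing)
    sdf = outside - inside  # negative inside, positive outside
    rng = np.random.default_rng(seed)
    # smoother along z: a re-segmenting rater redraws in-plane boundaries
    # but rarely disagrees about the slice extent of a smooth lesion
    disp = _grf(rng, sub.shape, corr_length_mm=(5.0, 5.0, 15.0), spacing=spacing)
    # systematic whole-boundary bias: a second rater tends to segment the
    # whole lesion slightly wider or tighter, on top of local wobble
    bias = rng.normal(0.0, 0.8)
    # bounded smooth squashing: typical displacement is a sizeable fraction
    # of the amplitude, maximum strictly below it
    disp = amplitude_mm * np.tanh(0.6 * disp + bias)
    out = labels.copy()
    out[box] = sdf < disp
    if not out.any():
        raise EmptyROIError(f"{amplitude_mm} mm perturbation emptied the mask")
    return LesionMask(labels=out)


def write_cohort(cohort: PhantomCohort, out_dir) -> Path:
    """Write NIfTI volume/mask pairs, a manifest CSV and a ground-truth CSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest_rows = []
    truth_rows = []
    for case in cohort:
        vol_path = out_dir / f"{case.case_id}_volume.nii.gz"
        m1_path = out_dir / f"{case.case_id}_mask1.nii.gz"
        write_volume(case.volume, vol_path)
        write_mask(case.mask_rater1, case.volume.spacing, m1_path)
        row = {
            "case_id": case.case_id,
            "volume": vol_path.name,
            "mask_rater1": m1_path.name,
            "label": case.label,
            "institution": case.institution,
        }
        if case.mask_rater2 is not None:
            m2_path = out_dir / f"{case.case_id}_mask2.nii.gz"
            write_mask(case.mask_rater2, case.volume.spacing, m2_path)
            row["mask_rater2"] = m2_path.name
        manifest_rows.append(row)
        gt = case.ground_truth or {}
        truth_rows.append({
            "case_id": case.case_id,
            "label": case.label,
            "true_mean_hu": gt.get("true_mean_hu"),
            "diameter_x_mm": gt.get("diameters_mm", (None,) * 3)[0],
            "diameter_y_mm": gt.get("diameters_mm", (None,) * 3)[1],
            "diameter_z_mm": gt.get("diameters_mm", (None,) * 3)[2],
        })
    write_manifest(manifest_rows, out_dir / "manifest.csv")
    write_manifest(truth_rows, out_dir / "ground_truth.csv")
    return out_dir
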