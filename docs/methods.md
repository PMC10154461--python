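# Methods

This note documents the models, conventions and numerical choices behind
`rimshrink`, in the order the pipeline applies them.

## ROI derivation

The input is a binary full-volume lesion mask aligned to a CT grid with
spacing (dx, dy, dz) in mm, axis order (x, y, z), z the slice axis.

* **MAX** restricts the mask to the z slice with the largest foreground
  area (voxel count × dx·dy). Ties break to the smallest z — deterministic
  and documented; ties are measure-zero on real data.
* **Erosion** keeps a voxel iff its Euclidean distance (mm) to the nearest
  *background voxel centre* exceeds the radius r; distances are computed
  with the exact Euclidean distance transform using the voxel spacing,
  within each slice for the 2D mode (`MAX_E`) and in 3D for `ALL_E`.
  r = 0 is the identity. A mask touching the grid edge sees no background
  beyond the edge, so the edge does not erode it. The implementation crops
  to the foreground bounding box expanded by ceil(r/spacing)+1 voxels per
  axis; every background voxel within r of any foreground voxel lies inside
  the crop, so thresholding the cropped transform is exact (verified against
  an all-pairs brute-force oracle).
* `MAX_E` erodes the already-selected slice; the maximum-area slice is not
  re-selected after erosion.
* The default radius is 3 mm and is configurable (1–2 mm variants are a
  config change, not a code change). Note that with 3.75–5 mm slice
  spacing a 3 mm radius cannot remove whole boundary slices — the nearest
  out-of-plane background centre is already ≥ 3.75 mm away — so 3D erosion
  at clinical slice thickness acts mostly in-plane plus on oblique corners.
* Derivation enforces the containments ALL_E ⊆ ALL, MAX_E ⊆ MAX ⊆ ALL and
  raises a typed error naming the method and case when an eroded ROI comes
  out empty. The pipeline excludes such a case from **all four** methods
  jointly, keeping the paired tests valid.

## Preprocessing and feature extraction

Order: optional HU window clamp → nearest-neighbour resampling → fixed-bin
discretization → features. All steps are deterministic.

* **Window** (level 40, width 400 by default; optional): values clamped to
  [level−width/2, level+width/2]. The default window is far wider than the
  attenuation range of soft-tissue lesions, so it normalizes without
  distorting them.
* **Resampling**: target spacing 3×3×3 mm; output grid has
  ceil(extent_mm/target) voxels per axis; each output voxel takes the input
  voxel whose mm interval contains the output voxel centre (equivalently
  the nearest input centre; exact half-way ties go to the containing,
  larger-index voxel). Image and mask use the same index map, so the mask
  stays binary. Verified per-voxel against a brute-force nearest-centre
  search.
* **Discretization**: min-anchored fixed bins,
  level(x) = floor((x − min_ROI)/25 HU) + 1, so levels are invariant under
  global HU shifts and the ROI minimum always maps to level 1.
* **First order (18)**: moments are population moments; kurtosis is the
  Pearson (non-excess) form; entropy and uniformity use the discretized
  histogram in bits; robust MAD uses the [P10, P90] subset. A constant ROI
  has skewness and kurtosis defined as 0 (logged).
* **Shape (14)**: mesh volume (divergence theorem) and surface area from a
  marching-cubes surface of the zero-padded mask at iso-level 0.5. The
  binary field is lightly smoothed (Gaussian, 0.7 voxel) before meshing to
  remove the staircase bias — a raw binary ball's surface area is ~9% high,
  a smoothed one is within ~1.5% — except for thin ROIs (< 3 voxels in some
  direction, e.g. single-slice slabs), which mesh the binary field
  directly. Axis lengths derive from the eigenvalues of the covariance of
  physical voxel centres with a d²/12 per-axis term (voxels as boxes), which
  also gives one-slice ROIs a well-defined slab thickness. Maximum 2D
  diameters are the largest in-plane centre-to-centre distances within any
  fixed-z (Slice), fixed-y (Column) or fixed-x (Row) plane. A single-voxel
  ROI falls back to closed-form box values (logged).
* **Texture (72)**: GLCM and GLRLM use distance 1, the 13 unique 3D
  directions, symmetric co-occurrence, and an unweighted mean over
  directions with at least one valid pair/run; GLSZM zones and the GLDM
  neighbourhood use 26-connectivity (GLDM dependence tolerance 0, the
  dependence size counting the centre voxel); NGTDM neighbourhood averages
  use in-ROI neighbours only, and voxels with no in-ROI neighbour are
  excluded. Logs are base 2. Degenerate conventions: zero-variance GLCM
  correlation = 1, flat-ROI NGTDM coarseness capped at 10⁶, single-voxel
  ROIs yield all-zero GLCM features (no pairs exist). Every one of the 72
  values is checked against an independent naive (explicit-loop)
  implementation to 1e-6 relative.
* **The 104-name registry** (18 FF / 14 MF / 72 TF with TF = 21+16+16+14+5)
  is data-driven (`registry.csv`). The GLCM set keeps 21 features by
  omitting the three classically redundant ones (dissimilarity ≡ difference
  average, the homogeneity duplicate of inverse difference, and sum average
  ≡ 2×joint average); MCC and sum-of-squares are also not in the set, which
  was fixed before any validation and never revisited.

## Stability screen and selection cascade

* **ICC(2,1)** — two-way random effects, absolute agreement, single rater —
  from the standard mean-squares decomposition, computed per feature on a
  paired-rater subset (any subset of re-segmented cases is accepted; its
  size is recorded). Features with ICC < 0.75 are excluded. Identical
  constant vectors define ICC = 1; zero total variance with non-identical
  raters is an error.
* **Univariate screen**: two-sided Mann–Whitney U per feature, keep
  P < 0.05. A uniform rank test is used for all features (rather than a
  per-feature normality decision) because 104 normality calls on small
  samples are themselves unstable; this is a documented choice.
* **RFE**: L2-regularized logistic base learner (C = 1) on standardized
  features, dropping the single smallest-|coefficient| feature per round
  until ceil(0.30 × n_entering) remain. The procedure is deterministic; a
  keep target below 1 keeps exactly 1 (logged).
* **LASSO, 1-SE rule**: 50-point log-spaced penalty path from the
  analytic λ_max = max|Xᵀ(y−ȳ)|/n down to λ_max/1000; stratified 10-fold
  CV (folds reduced only if a class has fewer members than folds) of the
  held-out binomial deviance with fold-internal standardization (no
  leakage); chosen λ = largest with mean deviance ≤ min + 1 SE; survivors
  are the nonzero coefficients. If the 1-SE penalty zeroes everything, the
  deviance-minimizing λ is used instead (logged). Each stage operates on
  the survivors of the previous one, so survivor sets are nested by
  construction and asserted at run time.
* **Model**: near-unpenalized maximum-likelihood logistic fit (L2 with
  C = 10⁸) on standardized survivors; coefficients larger than 30 in
  standardized units indicate separation and trigger a ridge-stabilized
  refit (C = 1, logged). The radiomics score is the linear predictor.
  Standardization constants come from training rows only.
* **Split**: stratified random split with overall train size
  floor(0.8 × n); per-class counts start at floor(0.8 × n_c) with the
  remainder assigned by largest fractional remainder. 237 cases yield
  exactly 189/48.

## Evaluation

* **AUC**: Mann–Whitney rank estimator with tie correction; 95% CI by
  DeLong's placement-value variance, clipped to [0, 1].
* **pAUC**: unstandardized trapezoidal area under the empirical ROC
  polyline restricted to FPR ∈ [0, 0.05] (specificity ≥ 95%), with exact
  clipping of the crossing segment; range [0, 0.05], perfect classifier
  0.05, all-tied scores 0.05²/2 = 0.00125. CI by stratified bootstrap
  (2000 replicates by default, seeded). Integrating the same polyline over
  [0, 1] reproduces the AUC exactly.
* **Operating points**: predicted-positive means score ≥ threshold;
  candidate thresholds are the distinct scores plus one above the maximum.
  "youden" maximizes sens+spec−1 with ties toward higher specificity, then
  the higher threshold; "spec95" takes the smallest threshold with
  specificity ≥ 0.95 (which maximizes sensitivity subject to the
  constraint). Sensitivity-at-spec95 comparisons between methods use
  thresholds chosen on the pooled sample.
* **McNemar** on paired correctness (restricted to positive cases when
  comparing sensitivities): exact two-sided binomial when the discordant
  count b+c < 25, else chi-square with continuity correction; b+c = 0
  gives P = 1.
* **Pairwise score comparisons**: two-sided Wilcoxon signed-rank on paired
  per-case scores within each class, over the 6 method pairs, Bonferroni
  multiplier 6, capped at 1.
* **Decision curves**: NB(t) = TP/n − FP/n · t/(1−t) on the grid
  0.01…0.99 (t = 1 excluded); treat-all NB = π − (1−π)·t/(1−t); treat-none
  ≡ 0. Model curves are data; only the closed-form reference curves are
  asserted in tests.
* The evaluation report is a pure function of serialized scores and
  labels; every table entry is recomputable from the `scores` payload it
  carries.

## The phantom: what it emulates, and what it does not

Each case is an axis-aligned ellipsoidal lesion on a uniform background,
voxelized at 1×1×dz mm with dz drawn per case from {3.75, 5.0} (clinical
cohorts mix both reconstruction thicknesses roughly evenly). Class
attenuation means are 20.2 HU (adenoma) and 37.4 HU (non-adenoma) — the
pooled medians reported for lipid-poor adenomas and non-adenomas — with a
9-HU between-case spread. Intra-lesion texture is a stationary Gaussian
random field (squared-exponential correlation; adenomas 3 mm/10 HU,
non-adenomas 6 mm/14 HU, giving the mild textural heterogeneity contrast
the model exploits). In-plane diameters are drawn from 20–42 mm (adenoma)
and 22–45 mm (non-adenoma) — broadly overlapping so that attenuation and
texture, not size, carry most of the class signal — and through-plane
diameters from 30–50 mm, so the polar cap slices (whose partial volume a
3-mm erosion cannot reach at 3.75–5 mm slice spacing) stay small relative
to the in-plane rim.

The surrounding tissue is the partial-volume mechanism: a per-case
attenuation drawn from a fat/organ mixture (−90 HU with probability 0.4,
+45 HU with probability 0.6, ±12 HU jitter). The whole volume is blurred
with an isotropic-in-mm Gaussian PSF (σ = 2 mm default; kernel σ divided
per axis by the spacing), which mixes this background into the rim voxels,
and white measurement noise (σ = 10 HU) is added. The ground-truth mask is
the pre-blur ellipsoid; the generator stores the true per-case lesion mean
for recovery tests.

The second rater is simulated by shifting the mask's signed distance by a
smooth random field: in-plane correlation 5 mm, through-plane 15 mm (a
re-segmenting rater redraws in-plane contours but rarely disagrees about
slice extent), plus a per-case systematic wide/tight bias, squashed through
amplitude·tanh(·) so the maximum boundary displacement is strictly below
the amplitude (1.5 mm default). Voxels farther than the amplitude from the
boundary provably keep their label. All randomness flows from a single
PCG64 seed; identical seeds give bit-identical cohorts.

The defaults were calibrated once so that the full pipeline reaches a
hold-out AUC near 0.9 on cohorts of 50–60 cases per class, then frozen.

**What passing phantom tests do and do not show.** The phantom reproduces
the partial-volume mechanism faithfully at the feature level: with a 2-mm
PSF and 50-HU contrast the eroded full-volume ROI's mean attenuation is
closer to the true lesion mean than the uneroded one in essentially every
phantom, and the stability of first-order, size-zone and grey-tone
features under rater perturbation is consistently higher for eroded ROIs.
At the *model* level, however, the eroded-vs-uneroded contrast is
intrinsically small in this design, for reasons worth stating plainly:
(1) rim contamination affects well under half of the voxels, so robust
statistics (median, percentiles) of the uneroded ROI remain clean and the
selection cascade reliably finds them; (2) contamination inflates the
between-case variance of uneroded features, which sits in the denominator
of the ICC and partly masks their within-pair instability; (3) min-anchored
25-HU binning makes the texture features of narrow-range eroded cores
sensitive to which voxel happens to be the minimum, costing the eroded
ROIs some GLCM/GLRLM stability. Replicate averages of hold-out AUC and
pAUC rank the eroded full-volume method at or above the uneroded one, but
the per-replicate margins are inside sampling noise, and the all-104-feature
mean ICC does not separate the eroded from the uneroded variants even when
several feature families individually do. Real cohorts differ from the
phantom in exactly the ways that may enlarge the contrast — irregular
margins, necrotic subregions raters avoid differently, scanner shifts
between institutions — none of which the ellipsoidal generator models.

## Problem sizes used in the validation suites

Feature-level oracle checks run on ~6³ ROIs (exhaustive naive references);
erosion oracle checks on 20 random blob masks; the partial-volume recovery
check on 50 phantoms; the replicated pipeline comparison on 20 cohorts of
60 + 60 cases with an 8:2 split; the selection-recovery check on 20
synthetic 104-feature tables of 200 cases. These sizes were chosen to make
the statistical assertions well-powered at desk scale while each suite
completes in minutes on one CPU.

## Known limitations

* Ellipsoidal, axis-aligned lesions; no irregular margins, necrosis,
  calcification or orientation variation.
* A single background attenuation per case; real rims mix several tissues
  around one lesion.
* NIfTI orientation matrices beyond voxel spacing are ignored (logged);
  DICOM ingestion is out of scope.
* The GLCM registry omission choice (which 3 of 24 classic features to
  drop) is one of several defensible 21-feature sets; the registry file
  makes alternates a data change.
* Erosion semantics are voxel-centre EDT thresholding; software packages
  with structuring-element morphology differ at the sub-voxel level (a
  per-axis box-erosion variant is available behind the same interface).
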