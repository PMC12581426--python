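# Methods

`sella3d` measures the sella turcica (ST) — the bony fossa of the sphenoid
that houses the pituitary gland — from 3D radiographic volumes, and relates
its morphology to skeletal classification in a cohort. This note documents
the model behind each stage, the defaults and why they were chosen, what the
synthetic generators do and do not emulate, and the numerical conventions.

## Measurement model

### Segmentation

Bone is segmented by intensity windowing on raw stored grayscale units (GU);
no Hounsfield calibration or rescale-slope handling is applied, because
clinical CBCT and many CT exports are not reliably calibrated. Two windows
are supported:

* **fixed clinical window** `[-728, 2047]` GU, applied uniformly to patient
  scans (default of `PipelineConfig`). Window bounds are *closed*; with
  integer GU data this makes thresholding idempotent and monotone (widening
  the window never removes voxels).
* **adaptive midpoint threshold** for uncalibrated micro-CT-like data: the
  lower bound is the arithmetic mean of a sampled bone intensity and a
  sampled soft-tissue intensity, the upper bound the volume maximum. This is
  the appropriate mode for the synthetic phantom, whose intensities are not
  on the clinical GU scale.

Structures not connected to the region of interest are removed by keeping
the 26-connected component containing an anchor point. 26-connectivity is
the permissive choice for bone continuity: thin oblique bridges (common in
the cranial base at clinical resolution) do not split the structure.

### Closure planes and cavity extraction

The ST is open cranially, and laterally where its borders are not ossified.
Each opening is sealed by a plane through three reproducible landmarks,
oriented so the sella midpoint is on the keep side. Planes carry a *kerf*
(cut thickness, default **0.1 mm**): voxel centres strictly within
`kerf / 2` of the plane are removed. The kerf is symmetric about the plane —
the only orientation-neutral reading of a trim of stated thickness.

The cavity ("positive model") is recovered by a 6-connected flood fill from
the sella midpoint through non-bone voxels, bounded by bone and by the
discard/kerf side of every closure plane. Face connectivity is deliberate:
a diagonal (26-connected) fill could slip through a one-voxel bone wall. If
the fill reaches any face of the volume, closure is incomplete and the
pipeline fails with an error naming the face rather than reporting a
corrupted volume.

Voxel membership everywhere is by *centre point*: a voxel belongs to the
side of a plane, or to the inside of a shape, that its centre is on. There
is no partial-volume weighting; this keeps every operation exactly testable,
and the accuracy cost is quantified by the convergence experiment below.

### Volumes and linear measures

`vol_t` is the voxel count of the cavity times the physical voxel volume.
The anterior/posterior split plane passes through the posterior clinoid
process, the dorsum sellae and the caudal extension of the ST floor; it is
applied with kerf 0 and boundary voxels (signed distance exactly zero) go to
the anterior side. Anterior and posterior volumes are computed from their
voxel counts and the total is their sum, so `vol_t = vol_a + vol_p` holds
*exactly* in floating point — the identity that defines the anterior volume.

The five linear measures are 3D Euclidean distances between named landmarks
(`length_ant/length_post`, the interclinoid points, `height_sup/height_inf`,
dorsum-posterior-cranial/tuberculum, sella-mid/nasofrontal suture). The
mid-sagittal "length" and "height" endpoints are explicit user-placed
landmarks rather than automatic extremal searches: the measurement protocol
defines them on manually placed, orthogonally verified points, and explicit
endpoints are reproducible and rigid-motion invariant to machine precision.
The "midpoint of sella" used by the cranial-base distance (CB) is the
supplied `sella_mid` landmark, not a computed centroid.

Measurement CSVs print one decimal (the convention of the clinical tables);
full precision is kept in the returned objects.

## Synthetic phantom

The phantom is a bone plate (default 1800 GU on 0 GU background, Gaussian
noise SD 50 GU) spanning the grid footprint, carrying a half-ellipsoid fossa
with semi-axes `a = 5.5` (width), `b = 5.0` (length), `c = 8.0` mm (depth)
that opens cranially at the plate top. The defaults approximate the adult
linear medians (width ≈ 11, length ≈ 10, height ≈ 8 mm); because a real
sella is not a half-ellipsoid, the phantom's volume (≈ 461 mm³) is below
typical adult total volumes — the phantom is a geometry oracle, not an
anatomical model. Two rectangular notches pierce the lateral walls so that
the lateral closure planes are functionally necessary: without them the
flood fill escapes and the leak detector fires.

Ground truth comes in two forms:

* the closed-form half-ellipsoid volume below the cranial plane,
  `(2/3)·π·a·b·c`;
* the *kept-region* volume — the half-ellipsoid truncated by the cranial
  plane at `z = −kerf/2` and the lateral planes at `|x| = x_L − kerf/2` —
  evaluated by 1-D adaptive quadrature of elliptic-segment cross sections
  (machine precision; cross-checked against Monte-Carlo rejection sampling
  in the tests).

The convergence experiment (`recovery_experiment`) voxelizes the phantom at
0.3 / 0.15 / 0.075 mm, each at several sub-voxel grid offsets, and runs the
full pipeline. Error against the kept-region truth is averaged as mean
|relative error| over offsets: a single grid placement makes the lattice
-count error a signed fluctuation whose size depends on alignment luck, and
offset averaging is the standard convergence-study remedy. Measured
behaviour: ≈ 2.1% → 0.55% → 0.29% mean error across the three spacings, and
the default-grid measurement at 0.15 mm lands within 3% of the closed form
(the ≈ 1.9% kerf bite plus ≈ 0.5% lateral trim form a constant,
resolution-independent offset between the two truths).

Landmarks are emitted in physical mm in the volume frame; the phantom is
axis-aligned and imposes no anatomical orientation convention.

## Modality degradation and the bias bench

`degrade` models a coarser acquisition as Gaussian blur (PSF FWHM in mm,
default one target voxel per axis) → box-average resampling onto the target
grid over the same physical extent → additive Gaussian noise. The identity
profile is a fixed point, and uniform regions keep their mean exactly.

`bias_experiment` scans jittered phantom "specimens" (default 5, semi-axes
jittered ±8%) at a micro-CT-like reference (0.15 mm isotropic) and at CBCT
(0.3 mm) and CT (0.47/0.47/0.6 mm) profiles. The reference is segmented with
the per-specimen adaptive midpoint threshold; the clinical profiles use a
fixed wide window whose lower bound sits a quarter of the way from soft
tissue to bone, emulating the deliberately inclusive fixed clinical window.
Under blur that threshold dilates bone into the cavity, so coarser
modalities *underestimate* the cavity — the direction observed ex vivo.
With the defaults the bench reads ≈ −1.5% (CBCT) and ≈ −4.7% (CT) against
the reference; only the direction and order of magnitude are meaningful,
since the published per-specimen magnitudes depend on real specimens and
scanners that no mechanistic blur model reproduces.

## Synthetic cohort

The cohort generator mirrors a design that *recruits by classification*:
each subject's Wits appraisal is drawn from a truncated normal supported on
its class interval (I: [−2, 2] mm; II: > 2 mm; III: < −2 mm), with the
location parameter solved so the truncated mean equals the published group
mean (0.5 / 5.4 / −8.9 mm; SDs 1.3 / 3.0 / 4.4). This keeps group counts
exact (30/30/30 by default) and labels consistent with covariates by
construction, while matching the group means — an untruncated normal would
misclassify 6–13% of subjects and a naively truncated one would shift the
means. The vertical (ML-NL: 16.6 ± 2.3 / 23.4 ± 1.6 / 32.8 ± 5.1°, counts
30/28/32) and transverse (Me-MSP: 1.0 ± 0.6 / 4.2 ± 2.0 mm, counts 57/33)
axes and the 44/46 sex split are generated the same way, independent of
sagittal class.

The anterior volume is `719.6 + shift(class) + 150·ε` mm³ with default
shifts 0 / +65.3 / −73.2 (class medians 719.6 / 784.9 / 646.4 mm³; the
residual SD is the median class IQR divided by 1.349). The posterior volume
(195 ± 75 mm³, truncated at zero) is class-independent — the published null
finding — so the anterior/posterior split is the only class-discriminative
volumetric signal, and `vol_t = vol_a + vol_p`. A within-class Gaussian
-copula coupling between the Wits percentile and the anterior-volume
residual is calibrated by a seeded internal simulation so the cohort-level
Spearman ρ lands near `spearman_target` (default 0.337); the class structure
alone already contributes most of that correlation.

What the cohort does *not* emulate: measurement error in the covariates,
age/sex interactions, non-normal within-class shapes, and any linear-measure
class effects (the linear measures are class-independent noise around pooled
medians). Passing cohort tests therefore demonstrates that the statistical
layer is calibrated and powered under the assumed group structure — not that
real anatomy follows these distributions.

Measured calibration at the defaults: the Kruskal–Wallis test on the
anterior volume of null cohorts (no shifts, no coupling) rejects at ≈ 3.6%
over 1000 replicates (the chi-square approximation is slightly conservative
at n = 30 per group), and the class-II-vs-III Dunn/Bonferroni contrast is
detected in ≈ 86% of effect cohorts.

## Statistics layer

* **Bland–Altman**: differences `x − y`, sample SD (n−1), limits of
  agreement `mean ± 1.96·SD`. The multiplier is fixed: it reproduces all ten
  printed intra/inter-rater rows at two decimals.
* **Classification**: closed intervals own their boundaries (Wits = 2 mm is
  class I, ML-NL = 26.5° neutral, Me-MSP = 2 mm symmetric).
* **Cohen's d**: equal-weight pooled SD `sqrt((s1² + s2²)/2)`; the published
  worked example (7.92 ± 0.84 vs 8.48 ± 0.30 → d = 0.89) verifies under this
  convention.
* **Sample size**: smallest n per group whose *exact* noncentral-t power
  (noncentrality `d·sqrt(n/2)`, df `2n − 2`) reaches the target. The normal
  approximation does not reproduce the published n = 28 at d = 0.89,
  α = 0.05, power 0.90; the noncentral-t computation does, and it matches
  the standard power-analysis solvers and a Monte-Carlo simulation in tests.
* **Kruskal–Wallis**: tie-corrected H with a chi-square p on k − 1 df
  (all-identical data is the degenerate H = 0, p = 1 case). The post-hoc is
  **Dunn's z-test** on pooled mid-ranks with tie correction, Bonferroni
  -multiplied and capped at 1 — the standard nonparametric follow-up; the
  protocol named only "Bonferroni post-hoc tests", so pairwise Mann–Whitney
  would have been an alternative reading.
* **Spearman**: Pearson correlation of mid-ranks with the t-approximation p;
  constant inputs are an error, not a NaN. Bit-exact agreement with any
  particular commercial implementation's tie conventions is not targeted.

## Numerical conventions and degenerate inputs

* Plane construction refuses landmark triplets with triangle area
  ≤ 1e−6 mm² and orientation points on the plane.
* Keep-side predicates are strict (`signed distance > kerf/2`), so a kerf of
  0 still removes centres lying exactly on the plane of a *clip*; the A/P
  *split* instead assigns zero-distance centres to the anterior side so the
  partition is exhaustive.
* ROI cropping preserves the physical frame exactly: voxel centres keep
  their world coordinates, so landmarks never need re-indexing.
* Grids are axis-aligned with per-axis spacing (anisotropic CT supported);
  volumes with non-identity direction matrices are rejected at read time.
* All randomness flows through explicit integer seeds
  (`numpy.random.default_rng`); identical spec + seed reproduces arrays and
  CSVs byte-identically.

## Problem sizes used by the test suite

The suite runs the convergence study at 0.3/0.15/0.075 mm with 6 grid
offsets per spacing, conservation on 100 randomized phantoms at 0.35 mm,
the bias bench on 5 specimens from a 0.1 mm native grid, 1000 null and 200
effect cohort replicates, and brute-force rank oracles at total n ≤ 8 —
sizes chosen so the entire suite completes in well under a minute of
numerical work while keeping every Monte-Carlo check comfortably away from
its decision boundary.

## Known limitations

* The phantom exercises geometry, not anatomy: no trabecular texture, no
  pneumatization, no curved non-ossified margins.
* The degradation model has no beam hardening, scatter, ring artifacts or
  projection physics; it cannot reproduce published per-specimen bias
  magnitudes, only their sign and rough scale.
* Landmarks are always supplied, never detected; inter-operator landmark
  variability is outside the package (the rater-pair generator only
  emulates its downstream statistical signature).
* Mesh-based (surface) volumetry and smoothing are not implemented; volumes
  are pure voxel counts.
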