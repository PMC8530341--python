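# Methods

`koashape` implements a segmentation-based biomarker pipeline for knee
osteoarthritis (KOA): morphometric measurements (MEAS) and low-dimensional
statistical shape encodings (LDSE) are computed per knee from multi-structure
label volumes and evaluated as predictors of radiographic grade
(Kellgren–Lawrence grade, KLG 0–4; medial/lateral joint-space narrowing,
mJSN/lJSN 0–3) and of clinical outcomes (incident KOA, total knee
replacement, TKR) under balanced Monte-Carlo cross-validation with linear
SVMs.  Real cohorts of this kind (e.g. OAI DESS MRI with expert-verified
segmentations) are access-restricted, so the package ships a first-class
synthetic cohort generator with planted, analytically known effects; every
claim the test suite makes is a claim about recovering planted structure or
matching an analytic/brute-force oracle.

## Anatomy and conventions

Label volumes use the fixed encoding 0=background, 1=FB (femoral bone),
2=TB (tibial bone), 3=FC (femoral cartilage), 4=mTC / 5=lTC
(medial/lateral tibial cartilage), 6=mM / 7=lM (menisci), recorded in every
NIfTI header.  Axes are 0=medio-lateral (ML), 1=antero-posterior,
2=inferio-superior; world coordinates are `index × spacing` (diagonal
RAS-style affine, no origin offset).  Right-knee convention: medial is the
negative ML direction; left knees are generated (and analysed) by mirroring
axis 0, which exercises all side-handling code paths.

## The synthetic generator

Each knee starts from six deterministic template meshes in a shared frame:
bones as capped cylinders (the femur with condyle bumps), cartilages as
thin oblate ellipsoids, menisci as C-shaped wedges with a trapezoidal
cross-section swept over a 220° arc.  Both meniscal rims are
vertical-walled so the axial footprint of the solid has full thickness
everywhere; a knife-edge inner rim would make planted footprint fractions
unrecoverable from voxelized data at any finite resolution.  The peripheral
meniscal rim sits exactly at the tibial-plateau edge, so baseline extrusion
is exactly 0 mm and any planted ML shift is recovered 1:1.

Disease is a scalar latent severity `s ~ Uniform(0, 1)` per knee.  It is
collapsed to one axis deliberately: acceptance is parameter recovery, not
biological realism.  Severity acts through four deterministic, closed-form
deformations (defaults in parentheses):

* cartilage thinning — SI scaling by `1 − shrink·s` (shrink 0.5, i.e. 50 %
  thickness/volume loss at s = 1, the order of magnitude of end-stage
  cartilage loss);
* volume-preserving meniscal flattening — SI scale `f = 1 − flatten·s`,
  in-plane scale `1/√f` (flatten 0.35);
* meniscal extrusion — outward ML translation `extrusion·s`
  (6 mm at s = 1; severe clinical extrusion is ≳ 5 mm);
* osteophyte-like bone bumps — radial displacement up to `bump·s`
  (3 mm), localized on the antero-posterior aspect near the joint line so
  the plateau's ML silhouette (the reference edge for extrusion
  measurement) is unaffected.

Each structure expresses the latent through its own noisy copy
`clip(s + ε, 0, 1)`, `ε ~ N(0, 0.15)` (`expression_noise_sd`).  Without
this, one structure's encoding carries all available information and
combining feature sets could only add noise; uneven expression across
tissues is both the realistic mechanism and the reason multi-structure
feature sets outperform single-structure ones, on synthetic and real
cohorts alike.  Exact planted-value tests run in the `ε = 0` limit.

Benign anatomical variation is planted as per-structure orthonormal
displacement-field modes (smoothed Gaussian fields, orthogonalized against
the template's infinitesimal rigid motions so Procrustes alignment cannot
absorb them), with strictly descending standard deviations
(2, 1, 0.5 mm) so the planted variance ordering is unambiguous for
shape-model recovery tests.

Grades are ordered-probit style: `grade = #{thresholds ≤ s + η}` with
`η ~ N(0, grade_noise_sd)`.  KLG thresholds are (0.2, 0.4, 0.6, 0.8);
JSN uses compartment-specific thresholds.  The default grade noise is 0.12
(≈ 60 % of one grade step): real KLG reading is rater-dependent (weighted
kappa between raters ≈ 0.56–0.67), and a near-noiseless label would make
every classification task trivially separable and the planted
task-difficulty ordering degenerate.  Outcomes follow a per-horizon
logistic link `P(event ≤ h) = logistic(β0_h + β1·s)` with ascending
intercepts; a single uniform draw per knee makes events nested across
horizons.  Incident-KOA outcomes are "not at risk" whenever baseline
KLG ≥ 2.  All randomness derives from the single cohort seed; identical
configs are byte-identical downstream.

What the generator does **not** emulate: MRI intensities and contrast,
segmentation errors, longitudinal within-knee trajectories, multi-factor
disease phenotypes, or realistic population covariance of anatomy.
Passing tests therefore demonstrate that the *pipeline* measures what was
planted under controlled conditions — not that the features would attain
any particular performance on clinical data.

## Voxelization

Masks are produced by scanline rasterization: one ray per (ML, AP) voxel
column, even–odd filling between triangle crossings, with ray origins
jittered by ~1e-6 voxel so rays never strike triangle edges.  A voxel is
labeled iff its center lies in a structure's interior — exact
voxel-center-in-interior semantics, no partial volume — which keeps volume
oracles analytic (a 10 mm cube at 1 mm spacing is exactly 1000 voxels).
Overlapping interiors raise an error naming the colliding pair.

## Surface extraction and measures

Surfaces are extracted per structure by marching cubes at iso-level 0.5 on
the binarized mask, padded with background.  The mask is pre-smoothed with
a small Gaussian (σ = 0.6 voxel; configurable, 0 disables): a raw binary
mask yields a staircase surface whose area overestimates a sphere's by
≈ 9 %, while σ = 0.6 keeps the analytic sphere-area error within ≈ 2 %
and cube enclosed-volume error within ≈ 4 % at 0.5–1 mm spacing.  The
sigma was fixed once against those two closed forms.  Larger kernels
round corners excessively; no mesh-level smoothing or decimation is done.
Absolute area values remain implementation-relative (meshing algorithms
differ); all area-based features are used comparatively.

Volume features use voxel counting; the divergence-theorem mesh volume
serves only as an independent cross-check (they agree within 5 % for
structures ≳ 20 voxels across).  Closedness of a mesh is defined strictly:
watertight *and* consistently oriented (every directed edge used exactly
once).

## MEAS features (14)

Six height-normalized volumes (`V_FC, V_TC, V_mTC, V_lTC, V_mM, V_lM`,
mm³/m — the unit is a documented choice; only "normalized by height" is
prescribed), two meniscal surface areas (mm²), two meniscal
area-to-volume ratios (1/mm, un-normalized volume), two meniscal
extrusions (mm), two tibial coverages (%).  Extrusion is operationalized
as the maximum, over AP voxel rows, of the ML overhang of the meniscus
footprint beyond the plateau footprint (TB ∪ compartment cartilage) on
the compartment's outer side, clamped at 0 so the generator's zero
baseline is exactly recoverable.  Whether the clinical reference should
be the bone or cartilage edge, and a single slice or the 3-D maximum, is
not settled; this contract is normative for the package and is what the
generator plants.  Coverage is the voxel-column footprint intersection
`100·|TC ∩ M| / |TC|`.  Missing inputs (absent label, missing height)
produce NaN markers; rows with any missing selected feature are dropped at
evaluation time, mirroring the discard rule used with real annotations.

## LDSE features

Corresponded meshes of one structure (one triangulation across the cohort;
correspondence is guaranteed by the generator and is out of scope for real
meshes) are aligned by generalized Procrustes analysis — rigid only, no
scale removal, because overall size (osteophytes, joint swelling) is
disease-relevant.  The shape model is PCA in the tangent space at the
mean — the linearization of principal geodesic analysis, first-order exact
for the small deformations involved, and with an exact eigen-oracle for
tests.  Modes are orthonormal vertex-displacement fields ordered by
explained variance; each mode's sign is fixed (largest-magnitude component
positive) for cross-platform reproducibility.  At most
`min(300, n−1, 3V−7)` *non-degenerate* modes are kept: modes below the
standard matrix-rank tolerance on the singular values, or beyond 99.9 %
cumulative explained variance, are dropped.  Synthetic cohorts span a
low-dimensional subspace, and near-zero-variance directions would
otherwise be inflated into pure-noise features by range normalization in
the evaluation stage; on real cohorts, whose spectra decay slowly, the
cutoff retains modes up to the cap.  Encoding projects an aligned shape onto the leading modes;
the combined encoding concatenates the first 75 coefficients of FB, TB,
mM, lM (zero-padded when fewer exist, logged).  Per-visit cohorts are
modelled independently; left knees are mirrored into the right-knee frame
so one model per structure covers both sides.

## Evaluation

Tasks follow a fixed grid: KLG groupings (5-class, [0,1]/2/[3,4],
[0,1]/[2–4], 0 vs 2, 0 vs 4), 4-class mJSN and lJSN, and incident-KOA /
TKR prediction within 1–5 years, each crossed with the feature sets MEAS,
LDSE-FB/TB/mM/lM, LDSE-COMB, and their "+ MEAS" combinations.  Incident
KOA is defined as reaching KLG ≥ 2 *with* joint-space narrowing within the
horizon, risk set restricted to KLG < 2 at the index visit; with
longitudinal grade records the label is derived from the visit sequence,
with generator cohorts the per-horizon outcome column is used directly.

Each task runs `n_repeats` (default 1000; scaled studies use fewer)
Monte-Carlo repeats: subsample every class without replacement to the
minority size (re-drawn per repeat, each repeat carrying an independent
child seed spawned from the master seed), split 90/10 stratified by class,
min–max normalize on the training split only (constant features map to 0,
logged), fit `LinearSVC` (squared hinge, L2 penalty, C = 1, one-vs-rest).
Classification reports balanced accuracy (macro-averaged recall — the
standard multi-class generalization of (sensitivity+specificity)/2) and
weighted kappa (linear disagreement weights by default, quadratic
selectable; the weighting scheme is reported with results).  Prediction
reports the Mann–Whitney AUC of the SVM decision margin — margins rather
than hard labels, since thresholded labels discard ranking information.
Results aggregate as mean ± SD over repeats; multi-cohort summaries use a
case-weighted mean.  A minority class under 10 cases makes a task
infeasible (raised, or skipped with a log line in grid runs).

Feature importance for TKR uses a single multivariable logistic regression
of the outcome on all 14 MEAS features, standardized to unit SD, reported
as per-SD odds ratios with Wald 95 % CIs.  Per-SD rather than per-raw-unit
ORs are a documented choice for comparability across mixed units
(mm³, mm, %); per-feature quasi-separation is flagged and the CI reported
unbounded.

## Numerical choices and degenerate inputs

* Rasterizer ray jitter 1e-6 voxel; odd crossing counts (open meshes)
  raise.
* Procrustes: iterate full-set rigid alignment to the evolving mean until
  the mean moves < 1e-6 mm RMS or 100 iterations; Kabsch with reflection
  guard.
* Shape-model rank tolerance: `s > s_max · max(n, 3V) · eps`.
* Kappa is computed on the fixed ordinal scale of the task (absent grades
  in a test split keep their position); a single distinct label in both
  vectors raises.
* SVM seeds: each repeat's child seed also seeds liblinear, so any single
  repeat is reproducible in isolation.

## Problem sizes used in tests and the acceptance script

Synthetic end-to-end studies use n = 300 knees at 1.0 mm isotropic
spacing with 50 Monte-Carlo repeats per task; planted-recovery and
morphometry oracles use 0.5 mm spacing on single knees or small cohorts;
shape-model recovery uses cohorts up to n = 200; null calibration uses
200 permutation repeats and n = 10 000 label pairs; odds-ratio recovery
uses n = 5 000 over 100 seeds.  These sizes are the package's default
demonstration scale; all are configurable upward.

## Known limitations

* Tangent-space PCA, not full Riemannian PGA; adequate for small
  deformations, untested for large ones.
* Surface correspondence is assumed, not established; real meshes need
  external registration before LDSE.
* The extrusion contract is package-normative (see above), not a validated
  clinical measurement.
* Synthetic grade distributions are a free configuration, not calibrated
  to any real cohort's class balance.
* Absolute surface areas depend on the meshing pipeline; only comparative
  use is supported.
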