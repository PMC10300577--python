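# Methods

This note documents the models, conventions and numerical choices behind
`mslat`, and what the synthetic phantoms do and do not establish about real
data.

## Synthetic longitudinal phantoms

Geometry is analytic by design: an ellipsoidal brain (default semi-axes
26×28×24 mm) with a 3-mm cortical shell, an ellipsoidal ventricular cavity
(8×11×7 mm), and spherical white-matter lesions, voxelised on a 64×64×20
grid of 1×1×3 mm voxels that mimics 2-D dual-echo acquisitions.  Every truth
value has a closed form — lesion event volumes are sphere-shell volumes,
global atrophy under a boundary scale factor *s* is 100·(s³−1)%, and
ventricular change is an ellipsoid-shell ratio — so downstream estimators
are validated against oracles that share no code with them.

Partial volume is modelled by linear mixing: each voxel's tissue coverage is
`clip(0.5 − d/w, 0, 1)` where *d* is the signed distance to the structure
surface and *w* the voxel footprint projected onto the surface normal.
This matters: with binary voxelisation the image edge moves in whole-voxel
jumps and profile matching acquires orientation-dependent biases of
~0.1–0.2 mm, an order of magnitude above the displacements being measured
(≈ 0.25 mm for 1% atrophy).  With linear mixing the edge profile shifts
continuously, as it does in real MRI.

Acquisition artefacts: per-slice multiplicative gain jitter along the slice
axis (SD 5%, mimicking interleaved 2-D acquisition), a smooth random
quadratic multiplicative bias field (±5%), additive Gaussian noise
(SD 20 ≈ 2.5% of WM on the PD channel), and per-site multiplicative
intensity offsets (SD 4%).  Lesions are PD-hyperintense at 400 intensity
units above WM (≈ 14 noise SD in the subtraction image); lesion
contrast-to-noise in the emulated trial is not published, so this default is
a free parameter, chosen high enough that event detection is
contrast-limited by partial volume rather than noise.

Cohort-level defaults follow the longitudinal structure reported for early
MS treatment trials: atrophy scale *s* ~ N(0.9987, 0.002) (PBVC ≈ −0.4%/y),
ventricular dilation ~ N(0.10, 0.10) mm (PVVC of a few %/y), lesion
birth/growth/shrinkage/death rates tuned to a baseline lesion load of
≈ 3–4 mL and a TLVC spread of ≈ 0.5 mL/y, age ~ N(31.5, 8.35), 61.7%
female, a 2:1 early:delayed treatment split, and per-interval conversion
status as a Bernoulli covariate.  Cohorts share one template grid —
inter-subject variation is parameter jitter (±4% brain radii), not
anatomical deformation — which removes the need for nonlinear registration
while preserving the statistical structure the voxel-wise and multilevel
analyses require.

When lesion–atrophy coupling is requested, each interval's ventricular
dilation receives an extra `coupling_beta × TLVC` mm of outward motion, so
the coupling is physically present in the images, and the generator records
the injected displacement and region as ground truth.

**What passing tests do not show about real data:** the phantoms have no
cortical folding, no realistic T1 tissue contrast beyond four tissue means,
no scanner physics (k-space artefacts, distortion, motion), identity
anatomy across subjects, and spherical lesions with clean boundaries.
Results here establish correctness of the computational chain and its
calibration under known truth — not clinical performance.

## Lesion-change quantification

The subtraction pipeline slice-corrects both PD volumes (per-slice
multiplicative gain matching of in-mask medians; medians chosen over means
for robustness to lesions; slices with < 50 brain voxels get interpolated
gains), forms the halfway-space difference `visit2 − visit1`, and Z-scores
it over non-lesional brain tissue (requiring ≥ 1000 such voxels;
σ = 0 rejected).  Inside the union lesion mask, |Z| strictly greater than
1.5 marks changing voxels (the threshold is strict by definition; the
default 1.5 SD is the method's operating point, configurable).

Event taxonomy uses 26-connected components per visit matched by ≥ 1 voxel
of overlap; many-to-many overlaps merge into one matched group (logged).
Components present only at follow-up with ≥ 1 increase voxel are *new*
(volume = the component's volume); only at baseline with ≥ 1 decrease voxel,
*disappearing* (volume at baseline); matched groups are *enlarging* or
*shrinking* by the sign of the net change-voxel volume over their union,
with the net volume as the event volume.  This accounting is the ledger the
TLVC formula implies; the minimum number of changing voxels per event
defaults to 1 (configurable), which means single-voxel noise events on
stable lesions are possible at the 1.5 SD operating point — they are small,
sign-balanced, and do not bias TLVC (the null-calibration test quantifies
this).  Positive Z inside lesion masks is read as growth because MS lesions
are PD/T2-hyperintense.

## Edge-displacement atrophy

Edges are boundary voxels of the brain (or ventricle) mask, with outward
normals from the gradient of a 1.5-mm-smoothed mask and optional sub-voxel
refinement to the intensity-gradient peak.  For each edge point, profiles
sampled at 0.5-mm steps over ±6 mm along the normal in both visits are
matched by NCC over shifts of ±4 mm with quadratic sub-sample refinement;
flat or weakly correlated profiles (peak NCC ≤ 0.5) are dropped, and a pair
is rejected if more than half drop.

Sign conventions: at the brain surface, inward motion (tissue loss) is
negative.  At the ventricular surface the displacement field stores outward
interface motion (enlargement) as positive — that is the PVVC convention —
while the rasterised whole-brain edge map used by the voxel-wise analysis
negates ventricular values so that *negative always encodes faster atrophy*
in the map, matching how edge-displacement images are read.

Volume change is integrated as `ΔV = Σᵢ dᵢ Σ_f (n̂ᵢ·ê_f) A_f` over the
exposed faces of the boundary voxels.  Projecting each face onto the local
normal makes the staircase surface converge to the true surface integral,
so no staircase-area calibration (≈ 1.5 for plain face counting) is needed;
a settable calibration scalar (default 1.0) is retained for data where the
edge model is imperfect.  PBVC = 100·ΔV/V over the outer brain surface;
PVVC = 100·ΔV_vent/V_vent with outward motion positive.  The T1 channel is
used after slice correction and lesion filling (local-mean fill with
matched noise, 5-voxel neighbourhood), so lesion evolution near edges does
not masquerade as surface motion.

## Registration

Rigid 6-DOF transforms are parameterised as xyz Euler rotations about the
mask centroid plus translation, optimised by multi-resolution Powell search
on masked NCC.  Both pyramid levels pre-smooth the images (σ 2.5 and 1.5
voxels): matching a crisp image against its own resampled copy otherwise
rewards interpolation-free integer-voxel shifts over the true pose — an
interpolation artefact, not a similarity signal.  A final check requires
the optimised similarity to be at least the initial one.

The halfway split takes the matrix square root: the rotation is halved
about its screw axis and the translation solves `(I + R_half)·t_half = t`,
so the halves compose exactly; each visit is resampled with half the motion
(trilinear for images, nearest for masks), giving both equal interpolation.
With visits generated on a shared grid (`register=False`), the halfway
resampling is a no-op rather than an interpolation.

## Voxel-wise inference

Displacement maps are prepared in the listed order: value-propagating
max-magnitude grey dilation (2 voxels; ties resolve to the positive value;
non-zero voxels keep their own value), masking with the template brain-edge
image (outer + ventricular boundary, dilated 2 voxels), Gaussian smoothing
(σ = 5 mm converted to voxels per axis, zero-padded boundaries), re-masking.

The design matrix codes site as cell means (one indicator per site, no
separate intercept — the indicators sum to the intercept), demeaned age and
the regressor, and sex as 0/1.  Interaction analyses use group-specific
slope columns with a difference contrast.  TFCE uses E = 0.5, H = 2,
26-connectivity, with per-map `dh = max/n_steps` (100 steps for standalone
enhancement, 50 within permutation loops; the oracle-equivalence test runs
at matched dh).  The implementation is an incremental union-find sweep over
descending thresholds — exact for the discrete threshold grid — compiled
with numba so 10⁵ TFCE evaluations stay cheap; tests verify it against an
independent per-threshold labelling oracle.

Permutation inference is Freedman–Lane: residuals of the reduced
(covariate-only) model are permuted and added back to the reduced fit, the
full model is refit, and the maximum TFCE statistic per permutation forms
the null; `p(v) = (1 + #{max ≥ obs(v)})/(n_perm + 1)`.  Tests are one-sided
in the contrast direction by default (flip the contrast for the other
tail); the pipeline runs a two-sided variant (max over both enhanced
tails vs |observed|).  Defaults follow the published analysis: 5000
permutations, α = 0.05, ≥ 15 significant voxels for reporting, with region
labels listed when ≥ 10% of significant voxels fall in an atlas region and
the peak at minimum p (ties by |TFCE|).  β > 0 maps to "Faster
Atrophy/Lower TLVC" and β < 0 to "Faster Atrophy/Higher TLVC" under the
atrophy-negative map convention.  The TLVC regressor enters in raw mL, so
β is in mm of edge displacement per mL.

In synthetic mode the template space is geometric: study template = mean of
99th-percentile-normalised baseline T1s of subjects selected across the
normalised-brain-volume distribution (NBV proxied by brain-mask volume
fraction); the atlas partitions the brain into six disjoint regions —
periventricular (≤ 8 mm from the ventricles), infratentorial (lowest fifth
of the z extent), and frontal/occipital/parietal/temporal by
anterior–posterior and superior–inferior position.  Real atlas masks can be
supplied by path; none are bundled.

The localisation experiment operates at a stated effect size: a pilot GLM
pass measures the realised per-voxel |t| in the coupled region and rescales
the coupling (damped multiplicative updates, up to 3 iterations) until the
mean |t| sits near 4, since sensitivity at a fixed FWE level is meaningful
only at a controlled operating point.

## Mixed models

`MixedLM` (statsmodels) with a random intercept for site and a variance
component for patient-within-site; REML for estimates, an ML refit for
interaction tests; Wald z p-values.  Random slopes are not modelled — the
three-level structure is intercepts-only, the simplest model consistent
with the clustering description.  Non-convergence raises; a singular site
variance triggers a two-level refit without the site intercept (flagged),
falling back to the three-level fit if the refit itself fails (small-sample
demos).  The pipeline drops covariates that are constant in a subset (e.g.
no converters in a small cohort) rather than fitting a singular design.

Study-question subsets: q1/q2/q3 use all rows (q2 and q3 add TLVC×treatment
and TLVC×CDMS interactions); q2a keeps delayed-treatment patients'
untreated years 1–2 (excluding interval-specific converters) plus their
treated years 4–5 with a two-level `period` factor; q2b keeps ET year 1 and
DT year 3, dropping DT patients who converted during years 1–2 (they
started treatment at conversion); q2c keeps ET years 2–5 and DT years 4–5.
`period` is modelled as a two-level factor with a TLVC×period interaction;
separate per-period fits are also available since the design description
supports both readings.  No multiple-testing correction is applied across
questions.

## Problem sizes and determinism

Verification experiments run at sizes chosen for single-CPU turnaround
while keeping each check statistically meaningful: Z-calibration on ≥ 10⁵
voxels; TLVC recovery on 20 subjects; taxonomy on 48 events; FWE
calibration on 200 null cohorts of 20 subjects on 24×24×12 grids with 500
permutations (the 95% binomial band around 0.05 at 200 replicates is
±0.030); localisation on 40 subjects with 500 permutations; mixed-model
coverage on 100 replicates of 10 sites × 20 patients × 4 observations and
interaction power on 50 replicates at the ±0.1-scale effect sizes typical
of treated/untreated slope contrasts.  Every random stage takes an explicit
seed; fixed seeds reproduce cohorts, permutation p-maps and pipeline CSV
outputs bit-identically.

## Known limitations

* PBVC/PVVC accuracy degrades for structures only a few voxels across
  (ventricular PVVC carries ~10–15% relative error at default geometry).
* Event volumes are counted in whole voxels; partial-volume rims inflate
  enlarging/shrinking volumes by up to ~30% per event at high
  contrast-to-noise (biases largely cancel in TLVC; recovery r ≥ 0.95).
* The rigid registration assumes mono-modal contrast (NCC); no nonlinear
  registration, distortion correction or skull stripping is provided —
  masks are inputs.
* Single-channel subtraction only; no spline resampling option.
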