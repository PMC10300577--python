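# mslat — concurrent lesion change and brain atrophy in longitudinal MRI

`mslat` quantifies how white-matter lesion activity and brain atrophy evolve
*within the same follow-up interval* in longitudinal brain MRI of early
multiple sclerosis, and tests where the two processes are spatially linked.
It is aimed at neuroimaging researchers who want a fully scriptable,
testable re-implementation of this analysis chain — from raw visit pairs to
voxel-wise statistics and multilevel models — together with a synthetic
longitudinal phantom generator so every stage can be validated against
closed-form ground truth without access to trial data.

## The measurements

**Total lesion volume change (TLVC, mL/year).**  The PD-weighted images of a
yearly visit pair are slice-corrected, rigidly registered to a common
halfway space (each visit resampled with half the motion, so both suffer
equal interpolation), and subtracted.  The difference image is converted to
Z-scores using the mean and SD over *non-lesional* brain tissue, which makes
the threshold robust to site and scanner intensity differences.  Voxels
inside the lesion masks with |Z| > 1.5 are labelled as changing; connected
lesions are matched across visits and classified as new, enlarging,
shrinking or disappearing; and

```
TLVC = (new + enlarging) − (shrinking + disappearing).
```

**Edge-displacement atrophy (PBVC / PVVC, %/year).**  At every brain-surface
and ventricular-surface voxel, 1-D intensity profiles along the outward
normal are matched between visits by normalised cross-correlation with
sub-sample refinement, giving a signed perpendicular edge displacement in
mm.  Integrating the displacement over the exposed boundary-voxel faces
(a discrete divergence-theorem surface integral) yields the percentage brain
volume change (more negative = faster global atrophy) and percentage
ventricular volume change (more positive = faster central atrophy).

**Voxel-wise association.**  Per-subject edge-displacement maps are dilated,
masked with a template brain-edge image, smoothed with an isotropic 5-mm-σ
Gaussian and re-masked.  A voxel-wise GLM (age, sex, site covariates;
TLVC regressor or TLVC×group interaction) is tested with threshold-free
cluster enhancement (E = 0.5, H = 2, 26-connectivity) and family-wise-error
corrected p-values from the Freedman–Lane permutation distribution of the
maximum enhanced statistic.  Clusters of ≥ 15 significant voxels (p < 0.05)
are reported with their atlas location, peak, and mean β.

**Whole-brain association.**  Yearly PBVC/PVVC is regressed on TLVC in a
three-level linear mixed model (observations within patients within sites;
random intercepts at both levels; REML), corrected for age and sex, with
TLVC×treatment, TLVC×CDMS-status and TLVC×period interactions, reported as
(B, SE, p).

## Worked example

```bash
python examples/02_lesion_change.py
```

```
non-lesional subtraction stats: mu=+8.60, sd=31.91
  lesion 1: enlarging    0.372 mL
  lesion 2: disappearing 0.138 mL
  lesion 3: new          0.126 mL
estimated TLVC: +0.360 mL/y (truth +0.256)
positive (new+enlarging) - negative (shrinking+disappearing): 0.498 - 0.138
```

The phantom carried one enlarging, one disappearing and one new lesion; the
subtraction method recovers all three with the right categories, and the
signed event-volume sum gives the yearly TLVC (the mild overestimate comes
from partial-volume voxels at event rims crossing the |Z| threshold).

```bash
python examples/03_atrophy.py
```

```
brain edge points : 4744
mean brain edge displacement: -0.247 mm
PBVC: -3.246 %  (truth -2.970)
PVVC: +10.32 %  (truth +11.15)
negative PBVC = global atrophy; positive PVVC = ventricular enlargement
```

A 1% uniform boundary scaling (true PBVC = 100·(0.99³−1) = −2.97%) moves the
brain edge inward by ≈ 0.25 mm; the surface-integrated displacement estimate
lands within half a percentage point, and the 0.3-mm ventricular dilation is
recovered within its analytic shell-volume truth.

The other scripts in `examples/` demonstrate phantom generation, halfway
registration, the voxel-wise TFCE permutation analysis, the three-level
mixed models and the end-to-end pipeline (`mslat run-all --config cfg.yaml`
from the shell).

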