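# Methods

`octvbm` applies the voxel-based-morphometry idea to macular optical
coherence tomography: every scan is spatially normalized to a common
target space so that the same grid cell refers to the same retinal
location in every eye, after which statistics are computed independently
at each voxel.  This note describes the model, the numerical choices,
what the synthetic generator does and does not emulate, and the known
limitations.

## Spatial normalization

A macular volume is a stack of B-scans (rows of the en-face grid), each
composed of A-scans (columns); the default geometry is 25 B-scans x
1024 A-scans over a 20 deg x 20 deg field with 240 um between B-scans
and 3.87 um axial sampling.  Normalization has three steps:

1. **Left-eye orientation.**  Right eyes are mirrored along the A-scan
   axis so the optic nerve head always lies on the low-column side.
   Mirroring permutes values within rows and is exactly invertible.
2. **Global 2D translation.**  The fovea — the thinnest point of the
   ILM-to-BM retina map — is the anchor landmark.  The map is smoothed
   with a Gaussian specified in *physical* units (default sigma
   400 um, converted to per-axis voxel sigmas) because the grid is
   strongly anisotropic: 1 voxel is 240 um between B-scans but only
   ~5.6 um along a B-scan, and an unsmoothed (or voxel-isotropic
   smoothed) argmin along the A-scan axis would be dominated by
   measurement noise.  The integer landmark is the smoothed argmin
   (ties: centroid of the minimum set, rounded).  For registration a
   *sub-voxel* landmark is used: the depth-weighted centroid of the
   smoothed sub-level set within 10 um of the minimum, restricted to
   the connected component containing the minimum.  Subject and target
   sub-voxel positions are subtracted first and the difference is then
   rounded to an integer translation, so any landmark bias shared by
   subject and target (e.g. the slight pull of the nasal RNFL gradient
   on the smoothed minimum) cancels before rounding.  The translation
   is integer-valued: registration never interpolates thickness values,
   and cells translated in from outside the field are flagged invalid.
3. **Per-A-line depth affine.**  At every en-face position a 1D affine
   `z -> a z + b` maps the subject's ILM and BM depths onto the
   target's exactly (two-point fit; degenerate A-lines with zero
   retinal span are flagged invalid).  The affine aligns depth
   *coordinates* for correspondence; layer-thickness values are **not**
   rescaled by `a` (configurable via `rescale_thickness`).  Rescaling
   would normalize away total retinal thickness, which the statistical
   model deliberately keeps as a per-voxel covariate.

The target space is either a designated reference scan or a cohort-mean
template (register all scans to a reference, average the aligned
ILM/BM surfaces, re-anchor once on the average).

## Voxel-wise statistics

At each voxel outside the central foveal exclusion zone (default radius
500 um, approximately the central ETDRS subfield — the pit region where
inner layers vanish and segmentation is least meaningful), the model

    thickness_v ~ intercept + group + age + sex + retina_v

is fitted by ordinary least squares across subjects, where `retina_v`
is the subject's total retinal thickness at that voxel.  Group effects
are tested with the contrast t statistic (two groups) or an omnibus F
(several groups, with pairwise disease-vs-control maps each corrected
as their own family).  Sex enters as a binary indicator; disability
scores are treated as continuous.  All fits are solved in one batched
normal-equations pass; per-voxel missing data is handled with 0/1
weights, and voxels with fewer valid subjects than design parameters
plus one are excluded and reported in `n_effective`.

Multiplicity is controlled in two stages, per layer map:

* **Benjamini–Hochberg FDR** at alpha = 0.05 over the family of all
  valid voxels of that map (BH rather than the conservative BY variant;
  neighbouring voxels are positively dependent, for which BH retains
  control).
* **Cluster-extent filtering**: connected components of surviving
  voxels (8-connectivity by default) smaller than 9 voxels — a 3x3
  footprint — are discarded.  Surviving clusters are labelled in
  decreasing size, ties broken by the top-left-most voxel.

The displayed difference map is the *raw* group mean difference (what
an overlay on the fundus image shows), while the covariate-adjusted
effect remains available as the group coefficient.  Percentage change
is computed from group mean maps as `(patient - control) / control x
100`, with control-mean-zero voxels flagged invalid.

Voxel-wise covariate regression (age, disease duration, disability)
reports the standardized regression coefficient — the slope of z-scored
thickness on the z-scored predictor, optionally adjusted — which equals
the per-voxel Pearson correlation when no adjusters are used, followed
by the same FDR + cluster procedure.

## Test–retest reliability

From repeated registered scans the package computes per voxel:

* **Sw**, the within-subject SD: `sqrt(mean over subjects of the
  within-subject variance)`; for two sessions `sqrt(sum d_i^2 / 2n)`.
* **CV** = Sw / voxel grand mean x 100 (defined from Sw, not as a mean
  of per-subject CVs, so the map decomposes the same way Sw does).
* **ICC**, fixed by default to the two-way random-effects, absolute-
  agreement, single-measurement form ICC(2,1) =
  `(MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)`; the consistency
  form ICC(3,1) is available by configuration.  Classification bands:
  >= 0.9 excellent, >= 0.75 good, >= 0.5 moderate, else poor.

The session-1 vs session-2 check is a per-voxel paired t-test pushed
through the identical FDR + cluster procedure; on a well-behaved device
nothing should survive.

## Synthetic cohorts

Patient-level OCT data cannot be redistributed, so the generator
produces scans with known ground truth.  The template is a smooth
anatomical caricature: every inner layer is multiplied by a pit factor
`1 - exp(-(r/750 um)^2)` so total retinal thickness has its unique
minimum at the fovea; RNFL rises linearly (4 um/mm) toward the optic
nerve head side; GCIPL is a 45 um base plus a perifoveal annulus
(28 um peak at r = 1100 um, width 600 um); INL is a flat 32 um; a
constant 180 um outer-retina block completes the ILM-to-BM span.  These
values put the standard summary parameters (macular RNFL ~1.0 mm^3,
INL ~1.05 mm^3, GCIPL ~1.7 mm^3 over the 20 deg field) in the range
reported for adult cohorts.  Boundary surfaces are rebuilt from the
(noisy) component thicknesses, so the anatomical surface order holds by
construction.

Subjects are template copies with an integer fovea jitter (default up
to +/-1 B-scan and +/-5 A-scans), optional focal effects (discs,
annuli, sectors; deltas sum where they overlap; masks recorded as
ground truth), and independent per-voxel Gaussian measurement noise,
default SD 1.5 um per layer component — inside the sub-3 um Sw
envelope that repeated-scan studies of this device class report.
Retest stacks draw one latent map per subject (between-subject SD,
default 5 um) measured k times with independent noise, so the ground-
truth ICC is `b^2/(b^2 + w^2)` and the ground-truth Sw is w.

What the generator does **not** emulate: speckle-realistic B-scan
intensities, spatially correlated segmentation error (available only as
an optional stress mode), microcystic oedema or other focal pathology
beyond additive thickness deltas, inter-eye correlation structure, and
real covariate-thickness relationships (covariates are drawn
independently of the maps, which is exactly what makes the null
calibration a null).  Passing tests therefore demonstrate the
*procedure* — exact registration recovery, calibrated error rates,
correct formulas — not performance on vendor data.

## Problem sizes and numerical choices

Simulation-based checks run on the native 25-B-scan grid cropped to 128
A-scans (the full 1024-column grid is used where registration itself is
the subject): 200 null replicates at n = 30+30 for the false-discovery
calibration, 50 full-grid subjects for registration recovery, 20 random
stacks for the least-squares equivalence (tolerance 1e-10), n = 50
retest subjects for variance-component recovery and 100 null retest
replicates at n = 10.  Degenerate inputs are always flagged, never
silently zeroed: invalid cells are NaN end to end, BH families are
restricted to valid voxels, and perfect fits (zero residual) map to
p = 0 rather than dividing by zero.

## Limitations

* The en-face translation is rigid; residual anatomical variability
  (axial-length scaling, cyclotorsion) is not modelled, matching the
  scope of a translation + per-A-line-affine normalization.
* Cluster-extent filtering controls the count of spurious small
  clusters but is not a formal cluster-level inference (no permutation
  or random-field null for cluster size).
* The per-voxel GLM treats eyes/subjects as independent; with both eyes
  of a subject included at eye level, standard errors are optimistic.
  The default eye policy averages the two eyes of a subject first.
* ICC estimates at n = 10 subjects are noisy; the maps are descriptive
  at that sample size.
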