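# Methods

## Phantom model

The phantom is the simplest geometry that produces all the regional
structure the pipeline measures: an axis-aligned ellipsoidal brain
(default semi-axes 26 × 29 × 24 mm on a 64³ grid at 1 mm³), whose outer
3 mm is a closed cortical gray-matter ribbon (defined by distance to the
brain exterior), two small ellipsoidal lateral ventricles at the core
(semi-axes 1.8 × 4.5 × 1.8 mm, centers ±4.5 mm off the midline), and
white matter in between. Axis-aligned planes split white matter into
frontal (anterior of +8 mm), occipital (posterior of −16 mm), temporal
(inferior part of the middle band, below −12 mm) and parietal (the
rest). There is no simulation of MRI physics: no bias field, partial
volume, or k-space artifacts; intensities are per-tissue means (CSF 30,
WM 100, GM 120, lesions 180) plus i.i.d. Gaussian noise.

**Geometry calibration.** The pilot preset states six group means that
must cohere: the three per-zone fractions per arm *and* the total
fraction per arm, where total = Σ_z frac_z · |zone_z| / |WM|. Solving
that 2-equation system for the zone-volume weights gives
|PV|/|WM| ≈ 0.06, |IC|/|WM| ≈ 0.59, |deep|/|WM| ≈ 0.35; the default
ventricle and brain sizes were chosen once so the phantom's weights land
near this point (achieved: 0.056 / 0.509 / 0.435, giving derived totals
2.15 % and 0.90 % against the stated 2.1 % and 0.9 %). A small phantom
legitimately has a proportionally large infracortical band: a 5 mm
sub-cortical shell covers roughly half the white matter of a brain-sized
ellipsoid scaled to a 64 mm grid.

**Lesion planting.** Lesions are unions of random-radius (1.2–3 mm)
balls intersected with the target zone, the final ball trimmed to its
nearest-to-center voxels so the planted voxel count equals
round(target% · |zone|) exactly. Ground truth is therefore recoverable
by voxel counting, and the per-zone achieved fraction is exact up to
rounding. Targets a zone cannot hold raise an error naming the zone.

## Segmentation

Per-axial-slice thresholding against normal-appearing white matter,
stacked to 3-D. The default spread statistic is robust
(median + k · 1.4826 · MAD, k = 3) rather than mean + k·SD because the
lesions sit inside the reference region: on a slice with lesion fraction
p and lesion–WM gap g, the moment threshold is ≈ mean + p·g +
k·g·√(p(1−p)), which exceeds the lesion intensity once p ≳ 0.1 and the
mask collapses. The median/MAD statistic tolerates lesion fractions up
to 50 % per slice. The moments rule is retained as an option. A slice
with an empty reference region falls back to whole-volume statistics.
Optional Gaussian pre-smoothing (`smooth_sigma_mm`) and a small-
component filter handle high-noise regimes: at noise equal to half the
lesion–WM gap, σ = 0.8 mm smoothing with k = 3 holds Dice ≈ 0.88
against planted masks, above the 0.84 intra-rater floor used as the
acceptance bound. In the cohort presets (noise SD 8 against a gap of
80) the filter (min 3 voxels) suppresses the rare supra-threshold noise
voxels, which matters because the smallest tracked quantity — the
non-AF infracortical fraction, 0.07 % ≈ 20 voxels — would otherwise be
inflated by false positives.

## Zoning

Band masks use `scipy.ndimage.distance_transform_edt` with the voxel
spacing as sampling, so distances are physical mm and anisotropic grids
are handled; unit tests pin the masks to exhaustive all-pairs distance
computations on small volumes. Membership is inclusive (d ≤ width,
"within 5 mm" read as a closed ball), making tie behaviour
deterministic. The periventricular band excludes the ventricle itself,
so width 0 is empty. Deep white matter is defined by subtraction. Where
the two bands overlap (thin white matter), precedence assigns contested
voxels to the periventricular band by default, matching the order in
which the masks are constructed; the alternative is selectable. The
infracortical width defaults to the 5 mm operational definition with
2 mm available, since both figures circulate for the U-fiber band.
Physical positions are index × spacing (0-based); all volumes of a
subject must share one grid — there is no resampling, and mismatch is a
hard error.

## Lacunae and stroke

A radiologist's caliper measurement is not reproducible in code, so a
detected component's diameter is its equivalent-sphere diameter
(6V/π)^(1/3); the gate is 2 ≤ d < 15 mm (strict above) and the
"stationary across slices" criterion becomes axial slice extent ≥ 2
(configurable). Retained lacunae are volumetrized with the sphere
formula on that diameter and tagged by the depth zone at their centroid
("deep-gray" outside zoned white matter). Stroke volumes are computed
from supplied diameters only (d₁ · d₂ · slices · thickness, correction
factor 1.0 by default, 0.5 for the ABC/2 convention); there is no
automated stroke segmentation.

## Cohort generator

Per-subject zone fractions are log-normal multipliers of the group mean
(coefficient of variation 0.5 by default — LA loads are strongly
right-skewed, with SD/mean near 1 in comparable cohorts; the exact
per-subject dispersion is a free parameter, not an empirical claim),
**normalized to unit sample mean within each group × zone**. This
moment matching is deliberate: the preset's purpose is to embody stated
group-level conditions, and at n = 17 an unnormalized CV ≈ 0.5–1
log-normal would leave the realized group mean 12–24 % away from its
nominal value as often as not, confounding pipeline error with sampling
noise. With dispersion → 0 every subject sits at the group mean. TICV
and demographics are Gaussian draws around the per-arm means; stroke
and lacunae volumes are planted in fixed numbers of AF subjects only.
Lobe cortical thickness is generated as
ρ · x̃ + √(1−ρ²) · ε + c · z, where x̃ is log total LA residualized on
TICV (z) and standardized, so the population partial correlation
(controlling TICV) equals the planted ρ — 0 everywhere except the
temporal lobe, where ρ = −0.37. The sample estimate varies across
seeds; recovery is checked by confidence-interval coverage, not
equality. All subjects share one phantom geometry; TICV enters the
statistics as a tabular covariate only, and anterior/posterior planted
fractions are derived expectations from the zone composition of each
compartment.

What passing recovery tests on these phantoms does **not** show:
robustness to registration error, bias fields, partial-volume
boundaries, anatomical variability of ventricles and sulci, or
non-ellipsoidal lesion morphology. The phantoms validate the
bookkeeping (zoning, fractions, gates, statistics), not the clinical
segmentation problem.

## Statistics

* Summary-statistic and raw-vector t-tests share one formula
  (pooled-variance default, df = n₁+n₂−2; Welch optional). Both-groups
  zero variance with equal means returns t = 0 by convention.
* Chi-square is Pearson without continuity correction; Mann-Whitney U
  is the x-side statistic with tie-corrected asymptotic p.
* The log screen is ln(x + 1) by default — the offset admits the exact
  zeros that stroke and lacunae volumes contain — and reports sample
  skewness and excess kurtosis against the [−1, 1] window.
* The mixed ANCOVA analyzes the within-subject part in an orthonormal
  contrast space: each of the k−1 contrast columns is modelled on
  intercept + centered covariate + effect-coded group, Type III sums of
  squares are pooled across columns, and the within error has
  (k−1)(N−g−1) df — reproducing the repeated-measures GLM bookkeeping
  of the major statistics packages (F(2, 62) at N = 34, k = 3, and
  F(1, 31) for the two-level anterior/posterior analysis). The
  covariate is centered so the region main effect is evaluated at the
  covariate mean. Between-subject effects use the subject means on the
  same design (error df N−g−1). Partial η² = SS_effect/(SS_effect +
  SS_error). Sphericity is assumed by default (uncorrected df);
  Greenhouse-Geisser is available behind a flag. Null simulations put
  the interaction type-I error at the nominal 5 %.
* Partial correlation is the residual method (both variables
  residualized on the covariate with an intercept), p from the t
  transform with n−3 df; the Fisher-z CI uses n−4.
* The cohort report applies t-tests to raw values in the demographic
  block (printed-table style), switches to U when even the log
  transform leaves the screen outside [−1, 1], and runs the inferential
  battery (ANCOVAs, follow-up zone t-tests, partial correlations) on
  log-transformed fractions. No multiple-testing adjustment is applied;
  α = 0.05.

## Problem sizes and numerical choices

Default phantoms are 64³ at 1 mm³; a full 34-subject pipeline run takes
about one second, so the acceptance script and the end-to-end tests use
the full preset. Distance-oracle tests run on ≤ 16³ volumes where the
all-pairs computation is exact and fast. Monte-Carlo calibrations use
500 null replicates (type-I error of the interaction) and 200 cohort
replicates (partial-r CI coverage). Thresholding uses strict `>`, so a
noiseless reference region segments to an empty mask; Dice of two empty
masks is defined as 1 (perfect agreement of empty segmentations avoids
0/0). Lesion-planting tolerance is ±10 % relative or ±0.05 percentage
points, whichever is larger, though the construction hits the rounded
voxel count exactly.

## Known limitations

* The cortical "ribbon" is volumetric; there is no surface
  reconstruction, so the infracortical band approximates a mesh-based
  boundary inflation volumetrically.
* Brainstem/cerebellum are absent; the phantom is forebrain-only by
  construction.
* The interaction effect in the preset cohorts is weak on the log scale
  because per-zone multipliers are drawn independently; the preset
  plants group *means*, not a specific interaction F.
* Lacunar detection assumes the dark-lesion mask is given (planted or
  traced); no intensity-based cavity segmentation is attempted.
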