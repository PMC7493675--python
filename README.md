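# leukozone

Regional quantification of leukoaraiosis (white-matter hyperintensities,
WMH) with the statistical battery of a two-group neuroimaging cohort
study, exercised end-to-end on synthetic FLAIR phantoms with planted
lesion loads.

Leukoaraiosis — bright white-matter abnormalities on FLAIR MRI — is a
marker of vascular brain injury whose *location* matters: lesions within
5 mm of the lateral-ventricle wall (periventricular), within 5 mm of the
cortical gray–white boundary (infracortical, where U-fibers run), and in
the deep white matter between them carry different interpretations. The
package is aimed at researchers who need a tested, reproducible
implementation of this depth-zoned volumetric workflow and its group
statistics, plus phantoms with known ground truth to validate it.

## What it computes

For each subject, LA load is quantified as a percentage of regional
white matter,

```
LA_region % = 100 · |LA ∩ region| / |region|
```

over the three depth zones (built with spacing-aware Euclidean distance
transforms, band membership d ≤ width), the anterior (frontal) and
posterior (parietal + occipital) compartments, and total white matter.
Lacunae are 26-connected dark lesions gated to equivalent diameter
2 ≤ d < 15 mm and ≥ 2 axial slices, volumetrized as spheres
V = (4/3)π(d/2)³; stroke volume uses the two-diameter convention
d₁·d₂·(slices × thickness). The cohort battery comprises independent t
tests (raw vectors or printed mean/SD summaries), chi-square, Mann–
Whitney U, TICV-controlled partial correlations, and a mixed-design
ANCOVA (group × region with TICV covariate) reporting F, p and partial
η² = SS_effect / (SS_effect + SS_error), with the repeated-measures GLM
df convention — F(2, 62) for 34 subjects × 3 zones.

Segmentation thresholds each axial slice at `median + k·1.4826·MAD` of
normal-appearing white matter (k = 3 by default; a classical
`mean + k·SD` mode is available), stacks the 2-D masks into 3-D, and
optionally removes small components.

## Worked example

The `"pilot"` cohort preset emulates a pilot study of 17 adults with
atrial fibrillation (AF) and 17 non-AF peers, with planted zone means of
15.6/10.8 % (periventricular), 2.1/0.6 % (deep) and 0.72/0.07 %
(infracortical):

```python
from leukozone import RunConfig, run_pipeline

planted, measured, report = run_pipeline(RunConfig(seed=1))
print(measured.groupby("group")[["total_pct", "pv_pct", "deep_pct", "ic_pct"]].mean().round(2))
```

```
        total_pct  pv_pct  deep_pct  ic_pct
group
AF           2.16   15.63      2.11    0.72
non-AF       0.90   10.83      0.60    0.07
```

Every group mean recovered through segmentation → zoning → metrics lands
within a few percent of its planted value (AF total 2.16 vs 2.1 planted,
infracortical 0.72 vs 0.72, …). The report object carries the battery;
e.g. the depth ANCOVA prints

```
Depth-zone mixed ANCOVA (covarying TICV)
  region               F(2, 62) = 504.702, p = 0.0000, partial eta2 = 0.942
  region_x_group       F(2, 62) = 0.501, p = 0.6083, partial eta2 = 0.016
```

(a large region main effect — periventricular load dwarfs the other
zones — and, on log-transformed fractions with independent per-zone
dispersion, a weak interaction), and the planted negative association
between temporal-lobe thickness and LA shows up as

```
  total~thickness_temporal         r = -0.481, p = 0.005
```

The same pipeline is scriptable from the shell:
`leukozone run --preset pilot --seed 1 --out out/`, with `phantom`,
`segment`, `zones`, `metrics` and `analyze` subcommands for the
individual stages.

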