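# microwear

Dental microwear surface texture analysis for gridded 3D height maps of
molar enamel wear facets.

Chewing drags abrasive food particles across enamel and leaves a
microscopic wear texture whose geometry records both diet and jaw/food
kinematics. This package implements the quantitative half of that
analysis for small-mammal (vole-sized) teeth: it takes oriented confocal
height maps of wear facets — or generates statistically realistic
synthetic ones — and turns them into the 18 areal surface texture
parameters of ISO 25178-2 that such studies analyse, then compares
parameter distributions between specimen groups (localities, seasons,
and the buccal T2 vs lingual T3 facet of the second upper molar) with
nonparametric tests.

It is aimed at researchers doing dental microwear texture analysis (DMTA)
who want a scriptable, fully reproducible alternative to point-and-click
metrology software, and at methodologists who need a controllable
synthetic testbed for texture parameters.

## What it computes

**Preprocessing** (in fixed order): mirror right-side scans in *x* so all
facets share one biological frame (+y = mesial, 90° = mesial direction),
extract square analysis sub-surfaces along the enamel band, subtract the
least-squares plane z − (a + bx + cy), then denoise with a 5×5 median and
a 3×3 Gaussian filter. The per-specimen value of each parameter is the
median over its four sub-surfaces (circular median for the texture
direction).

**Spatial parameters** from the areal autocorrelation function
ρ(τ) of the levelled surface:

- *Sal* — autocorrelation length: min over directions of the lag where
  ρ first falls to s = 0.2;
- *Str* — texture aspect ratio: fastest/slowest decay distance ∈ [0, 1]
  (1 = isotropic);
- *Std* — texture direction: the lay angle, perpendicular to the
  direction of maximal spectral energy, in [0°, 180°).

**Hybrid parameters**: *Sdq* = RMS gradient, *Sdr* = developed
interfacial area ratio 100·(mean √(1+z_x²+z_y²) − 1).

**Functional parameters** from the areal material ratio
(Abbott–Firestone) curve ζ(r): *Smc* (inverse material ratio at p = 10 %)
and the volumes Vm, Vv, Vmp, Vmc, Vvc, Vvv at the standard p = 10 %,
q = 80 % anchors.

**Feature parameters** from watershed motif segmentation with Wolf
pruning at 5 % of the height range: *Spd* (peak density), *Spc* (mean
peak curvature −(z_xx+z_yy)/2), *Sha*/*Sda* (mean closed hill/dale area),
*Shv*/*Sdv* (mean hill/dale volume relative to the bounding saddle).

**Statistics**: per-parameter Wilcoxon–Mann–Whitney location tests
(normal approximation without continuity or tie correction by default;
exact enumeration and tie-corrected variants available) and Levene
dispersion tests, with Shapiro–Wilk screening. P values are reported
unadjusted — by design there is no multiple-comparison correction
anywhere in the output schema.

## Worked example

```python
import numpy as np
from microwear import (
    gen_cohort, compute_parameter_set, compare_groups, u_normal_pvalue,
)
from microwear.synthetic import facet_contrast_cohort
from microwear.pipeline import process_cohort

# A synthetic study cohort with the facet contrast template:
# 34 buccal (T2) vs 49 lingual (T3) facets, four 10x10 µm sub-surfaces each.
cohort = gen_cohort(facet_contrast_cohort(seed=11, grid=64))
records = process_cohort(cohort, parameters=["Std", "Str"])

from microwear.iso25178 import circular_median_180
for facet in ("T2", "T3"):
    std = circular_median_180([r.parameters["Std"] for r in records if r.facet == facet])
    s = np.median([r.parameters["Str"] for r in records if r.facet == facet])
    print(f"{facet}: median Std = {std:5.1f} deg, median Str = {s:.3f}")

table = compare_groups(records, "facet_autumn", parameters=["Std", "Str"])
print(table.to_dataframe()[["parameter", "U", "P_location"]])

# P value from a printed U statistic and the group sizes alone:
print(f"U=367, n=32/17 -> P = {u_normal_pvalue(367, 32, 17):.3f}")
```

prints

```
T2: median Std = 111.1 deg, median Str = 0.404
T3: median Std =  77.4 deg, median Str = 0.267
  parameter       U    P_location
0       Std  1634.0  1.195296e-13
1       Str  1639.0  8.418809e-14
U=367, n=32/17 -> P = 0.046
```

The buccal facet reads a lay direction near 110° with a more isotropic
texture (higher Str), the lingual facet near 79° with a more striated
one, and the facet contrast is overwhelmingly significant at these group
sizes. The last line shows the worked-example mode: the two-sided P of a
Mann–Whitney U under the no-tie normal approximation, computable from a
published U and the group sizes alone.

There is also a CLI: `microwear simulate | process | compare | run`
(see `microwear --help`), driven by a small YAML config.

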