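# Methods

This note documents the models, estimators, conventions and numerical
choices behind `microwear`, and what its synthetic testbed does and does
not establish about real confocal data.

## Data model and conventions

A surface is a regular grid of heights `z[j, i]` in µm with lateral
spacings `dx, dy` (µm/pixel), a validity mask for non-measured points,
and an orientation frame. After side standardization, +x is the
buccal-to-lingual axis and +y the mesial direction; angles are measured
counterclockwise from +x in [0°, 180°), so a purely mesial texture
direction reads 90°. Right-side scans are mirrored in x before any
analysis so left and right molars share one frame; mirroring maps a lay
angle θ to 180° − θ.

Invalid points are never interpolated or filled. Every estimator either
uses valid points only (levelling, material-ratio curve, gradients,
motifs) or requires a fully valid window and otherwise reports the
parameter as missing (the ACF-based parameters). Missing values propagate
through aggregation (a specimen value exists when at least half of its
sub-surfaces provide one) and are dropped pairwise in the statistics.

## Preprocessing chain

Order is fixed: mirror → extract sub-surfaces → per-sub-surface
(level → median 5×5 → Gaussian 3×3). Levelling subtracts the ordinary
least-squares plane over valid points; it is idempotent and makes the
chain invariant to adding any plane or constant offset. The Gaussian
uses a truncated 3×3 kernel with σ = 0.8 px, a conventional default for
that support; the exact cut-off of commercial implementations is not
recoverable, so σ is exposed in `PipelineConfig`. Both filters treat
borders by reflection (no data invented outside the window) and handle
masks explicitly: the median ranks valid neighbours only, the Gaussian
renormalizes its weights over valid neighbours (normalized convolution).
Whether levelling should precede or follow window extraction is genuinely
ambiguous in descriptions of this workflow; here each extracted window is
levelled independently, which is also what makes the window a
self-contained evaluation area. The choice is logged with every run.

## Areal autocorrelation, Sal and Str

The ACF is estimated with the circular (FFT/periodogram) method standard
in areal topography software, normalized to 1 at zero lag, and averaged
over a 3×3 grid of 50 %-overlapping blocks of half the window size
(Welch averaging). Two points motivated this estimator:

* a linear, overlap-normalized estimator (also available via
  `compute_acf(..., estimator="linear")`) carries an oscillatory
  doubled-frequency bias of order 1/(m·sin a) on narrowband (striated)
  surfaces, which is ~3 % at the window sizes used here — larger than
  the discretization error of the circular estimator on ridge textures
  with whole periods in the window;
* single-realization directional noise in the ACF biases the extremes of
  the decay distances that define Sal and Str; segment averaging reduces
  that variance roughly by the number of effectively independent blocks
  while leaving whole-period ridge ACFs exact.

Decay distances are measured on rays at 1° steps with bilinear
interpolation of the ACF and linear interpolation of the crossing of the
threshold s = 0.2 (the ISO default). The ray profiles are smoothed across
angle (Gaussian, σ = 3°, periodic) before crossing detection: the
decay-distance-vs-angle curve is stationary at its minimum and maximum,
so the smoothing bias at the extremes is second-order while the variance
reduction is substantial. Sal is the minimum distance over directions;
Str is minimum/maximum. When some direction never decays inside the
largest measurable lag (strongly striated surfaces), the slowest distance
is censored at that lag and the Str value is flagged; a surface whose ACF
decays in no direction has both parameters undefined.

## Texture direction Std

The spectral energy of the Hann-windowed, zero-padded (4×) surface is
resampled onto a polar (angle, radius) grid and integrated over radius
with the annulus Jacobian. Polar resampling matters: binning Cartesian
frequency pixels by angle makes bins near 0° and 90° far narrower than a
pixel, which piles whole axis-aligned pixel columns into single bins and
snaps peaks onto the axes. The angular spectrum is smoothed circularly
(σ = 1°), the peak located with parabolic sub-bin interpolation at the
configured 0.5° resolution, and the lay reported perpendicular to the
energy-maximizing frequency direction. On clean ridge fields the
estimator recovers the lay within ~0.5° and is rotation-equivariant
within ~1°; with realistic noise and bumps the per-window error grows,
which is why specimens aggregate four windows by the circular median on
the 180°-periodic circle (largest-gap cut, then ordinary median; gap ties
resolve toward the smaller angle).

## Material ratio and volumes

The areal material ratio curve is the empirical distribution of heights:
ratio(c) = % of valid points with z ≥ c, with midpoint plotting positions
and linear interpolation of the inverse ζ(r). Smc = ζ(p). Volumes follow
the standard anchor construction with p = 10 %, q = 80 %:
Vm(r₀) = (1/100)∫₀^{r₀}(ζ(r) − ζ(r₀))dr, Vv(r₀) = (1/100)∫_{r₀}^{100}
(ζ(r₀) − ζ(r))dr, integrated by the trapezoid rule on a 2001-point ratio
grid; Vmp = Vm(p), Vmc = Vm(q) − Vm(p), Vvc = Vv(p) − Vv(q), Vvv = Vv(q),
and the reported Vm, Vv are the values at p.

## Motif segmentation and feature parameters

Hills are watershed catchments of the inverted surface seeded at its
h-maxima, dales the same on the negated surface, with 8-connectivity.
The h-extrema reconstruction implements Wolf pruning exactly: a summit
whose dynamic (height above its connecting saddle) is below
h = 5 % of the surface height range does not seed a motif and merges into
its neighbour. Peak count is therefore nonincreasing in the pruning
fraction, and hills of z are identically dales of −z. A constant surface
has zero motifs (Spd = 0, other feature parameters missing).

Each motif's bounding saddle is the best pour-over height to a
neighbouring motif (the highest of pairwise boundary minima for hills);
a motif with no neighbour pours over the window border at its lowest
border point. Motif volume is integrated above (hills) / below (dales)
the bounding saddle. "Closed" motifs are catchments that do not touch the
window border, used for the area parameters Sha/Sda per their name; a
single motif spanning the whole evaluation area counts as closed, since
border contact is vacuous when there is no neighbour. Whether the volume
parameters should also be restricted to closed motifs is not settled in
the workflow this package emulates; volumes here use all motifs and the
flag is exposed. Peak curvature fits a full quadratic to the 3×3
neighbourhood of each summit and reports −(z_xx + z_yy)/2 averaged over
surviving peaks.

## Statistics

The location test is the Wilcoxon–Mann–Whitney U via midranks. The
default P value uses the large-sample normal approximation with the
no-tie variance n₁n₂(n₁+n₂+1)/12 and no continuity correction — the
variant that reproduces, to the printed precision, P values published
alongside U statistics in this study design (e.g. U = 367 at n = 32/17
→ P = 0.046). Options: tie-corrected variance, and exact enumeration of
all labelings for n₁+n₂ ≤ 14. Dispersion uses classic Levene (deviations
from the group mean; the Brown–Forsythe median variant is available),
and Shapiro–Wilk is provided for normality screening. P values are never
adjusted for multiplicity, and the output schema deliberately has no
adjusted-P column. The three study contrasts are locality (lingual facet,
autumn; 32 vs 17), season (lingual facet; 49 vs 5 — reported
descriptively only, the spring group being too small to test), and facet
(autumn, localities pooled; 34 vs 49).

## Synthetic surfaces and cohorts

`gen_surface` models a wear texture as: an oriented sinusoidal ridge
field (lay θ, wavelength 2.5 µm by default) + band-limited Gaussian noise
with anisotropic correlation lengths (across-lay/along-lay ratio =
`anisotropy`, which maps approximately onto measured Str) + Gaussian
bumps placed with ≥ 2.5σ mutual separation (distinct hills, so planted
bump density is recoverable as Spd) + white measurement noise + an
optional random tilt removed again by levelling. The default grid is
256×256 px over 10×10 µm. All draws come from one seeded generator;
identical seeds give bit-identical surfaces.

`gen_cohort` draws specimen-level texture parameters from per-group
distributions and emits raw, as-scanned maps (right-sided specimens are
stored mirrored so the pipeline's side standardization is exercised).
The default facet template anchors the lingual/buccal contrast at lay
means 79°/110° (specimen SD 10°), anisotropy 0.24/0.33, and
fewer-but-larger bumps on the buccal facet, calibrated once so that the
pipeline's measured medians land near Std ≈ 79°/110° and Str ≈ 0.3/0.4 at
group sizes 49/34 — the regimes this study design reports — with the
facet contrast detectable at those sizes. The template is a testbed
design choice, not a biological claim.

What the generator does **not** emulate: instrument artifacts (spikes,
dropouts correlated with slope), multi-scale roughness beyond one
correlation length, curvature of the underlying facet, or spatial
correlation between sub-surfaces of one specimen (they are independent
draws). Passing tests therefore demonstrate correctness of the
estimators and calibration of the statistics under a controlled texture
model, not instrument-level fidelity.

## Problem sizes and determinism

Replicated simulation checks (type-I calibration on null cohorts,
detection-rate studies) run on reduced windows — 32–64 px analysis
windows rather than 256 px — keeping each cohort replicate a few seconds
while preserving the estimators' behaviour; single-cohort results in the
worked example and the acceptance script use 64 px windows with the full
34/49 specimen design. Every random quantity flows from an explicit seed
through numpy's PCG64 generator; reruns are bit-identical, and the
pipeline writes every decided default (filter sizes, σ, thresholds,
seeds) to its run log.

## Known limitations

* ACF-based parameters require a fully valid window; masked scans
  currently yield missing Sal/Str/Std rather than a masked ACF estimate.
* Sal/Str depend mildly on the Welch segmentation depth for broadband
  textures (bias ↓, lag range ↓ with more segments); the default (2) is
  a compromise exposed in `compute_acf`.
* Str on strongly striated surfaces is censored by the measurable lag
  range and is best read jointly with its censoring flag.
* The watershed tie-break on plateaus follows scikit-image's
  deterministic raster order; exactly tied plateau pixels may be
  assigned differently by other implementations.
* Exact Mann–Whitney enumeration is limited to n₁+n₂ ≤ 14; beyond that
  the normal approximation (optionally tie-corrected) applies.
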