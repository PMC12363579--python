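# Methods

This note documents the statistical model behind `fxtrend`, the calibration
of the synthetic cohort generator, the numerical choices made where the
design was genuinely open, and what the test suite does and does not
demonstrate about real clinical data.

## Data model

One record per (patient, fraction, parameter): the value recalculated on the
day's anatomy and its planning-CT baseline. Fractions are 1-based (1..F,
F = 30 by default); all analyses run on percent deviations from baseline,
stored in percent units (−9.79 means −9.79 %). The deviation at a
hypothetical fraction 0 is identically zero by definition of the baseline.
Missing fractions are masked, never imputed: trend fits, per-fraction tests
and DTW all operate on the present points only. The parameter vocabulary is
closed (7 volumes, 7 dose measures) and case-sensitive; volumes are cm³,
doses Gy.

## Synthetic cohort generator

The generator emulates a 40-patient, 30-fraction thoracic cohort. The percent
deviation of patient *i* at fraction *f* for one parameter is

    d_if = α + β f + b_i + ε_if

with `b_i ~ N(0, σ_b²)` a persistent patient offset and `ε_if` a stationary
AR(1) process (ρ = 0.3 by default) whose marginal SD is `s₁` for the stable
majority cluster (65 % of patients) and `s₂ = 3 s₁` for the high-variability
minority. A fixed number `⌊rate · N · F⌋` of uniformly chosen points per
parameter (rate 0.04 by default) have their noise term replaced by a
high-leverage spike of ±6 pooled residual SDs. Absolute record values are
reconstructed as `plan · (1 + d/100)`, with per-patient planned baselines
drawn from published cohort characteristics (target volumes) or typical
thoracic planning values (OAR volumes and dose levels); baselines only set
the absolute scale and cancel from every analysis.

### Calibration

The published cohort trend table reports, per parameter, the course-average
deviation, the per-fraction rate, and its 95 % CI. These pin down the
generator's moments in closed form, and the defaults are computed from them
at import time rather than hard-coded:

* **slope** β = published rate (% per fraction);
* **intercept** α = average − β · 15.5, because the mean of a linear ramp
  over f = 1..30 is α + β (1 + 30)/2;
* **residual SD.** The sampling SD of a fitted cohort slope under the
  generator is `σ_e κ / √(N Sxx)`, where `Sxx = Σ(f − 15.5)² = 2247.5` and
  `κ² = wᵀRw / wᵀw` is the slope-variance inflation from AR(1) residual
  correlation (κ = 1.317 at ρ = 0.3, F = 30). Setting this equal to the
  printed CI half-width hw / 1.96 gives `σ_e = (hw/1.96)·√(N Sxx)/κ`, so a
  trend fitted to a simulated cohort reproduces the printed CI width. One
  printed CI has zero width at printed precision; its half-width is floored
  at 0.0025, half the table's last printed digit.
* **noise split.** The pooled residual SD is allocated as
  `σ_e² = p₁ s₁² + p₂ (3 s₁)²`, so `s₁ = σ_e / 1.949` at p₁ = 0.65.
* **patient offsets** are not constrained by the published table;
  σ_b = σ_e/3 by default — between-patient heterogeneity in the average
  deviation is taken to be modest relative to interfractional noise.

Parameters the generator does **not** attempt to match: cross-parameter
correlation (tumour shrinkage driving lung dose is not modelled — each
parameter is generated independently), calendar-time structure (weekend gaps
are ignored; the time axis is fraction index), and any nonlinearity of the
trend. CTV D95 deviations are defensively rescaled in the rare case the
per-fraction cohort mean leaves ±1 %, preserving the published
target-coverage behaviour.

### A consequence of linear calibration

The published table also reports the earliest fraction with a significant
deviation (5 for GTV volume). Under a *linear* trend calibrated to the
printed average and rate, the GTV mean deviation is already −5.0 % at
fraction 1, and with noise calibrated to the printed CI width the
per-fraction test's noncentrality at fraction 1 is ≈ 7.4 against a critical
value of 3.38 — so the detection onset is fraction 1, deterministically.
Reproducing an onset at fraction 5 would require cross-patient SDs near
11 %, contradicting the printed CI widths (which imply ≈ 4 %) and destroying
the average-deviation calibration; even then the onset estimate would have a
sampling SD of several fractions. The published onset therefore implies
sub-linear early deviations in the real cohort, which a linear generator
cannot represent while also matching the average, rate and CI columns. The
pipeline reports the onset it actually computes; this is a documented limit
of the linear-trend emulation, not of the detection rule.

## Trend analysis

* **Pooled OLS and influence screening.** Deviation is regressed on fraction
  over all patients; Cook's distance (p = 2 parameters) flags points above
  4/n, with flags capped at the 6.2 % ceiling (74 of 1200) — if more exceed
  the threshold, only the top ⌊0.062 n⌋ by distance are flagged. A perfect
  fit has zero influence everywhere by convention. Screening applies to the
  pooled regression stage; the mixed model is fitted to all points.
* **Mixed model.** `d ~ fraction` with a Gaussian response and a random
  intercept per patient, fitted by REML (statsmodels MixedLM). The reported
  95 % CI is a Wald interval with a cluster-robust sandwich SE over patients
  (CR1 small-sample factor, computed from the fitted variance components):
  within-patient serial correlation beyond the random intercept — present in
  the generator and expected in real repeated measures — would otherwise
  leave the model-based CI anticonservative (~86 % coverage instead of
  ~95 %). The model-based CI remains available (`robust=False`). On balanced
  data the fixed-slope estimate coincides with pooled OLS, which also serves
  as the fallback when the mixed fit is singular (e.g. zero residual
  variance); singular fits are flagged, not hidden.
* **Per-fraction tests.** A two-sided one-sample t-test of mean deviation
  against zero at each fraction, across the patients with data there
  (fractions with fewer than two contributors are masked). The Bonferroni
  family is the F fractions within one parameter, threshold α/F; the
  earliest significant fraction is the smallest f with p < α/F, or none.
  Whether the published onsets came from separate per-fraction tests or from
  mixed-model contrasts is not stated in the source; the t-test is the
  default and the construction is isolated behind one function so a
  contrast-based variant can be swapped in.

## DTW and clustering

* **DTW.** Classic dynamic-programming DTW. Default step pattern
  `symmetric2` (diagonal steps weighted twice, initial cell once), no
  window, no normalisation — the defaults of the established time-series
  clustering packages; `symmetric1`, a Sakoe–Chiba radius and path-length
  normalisation (weight n + m) are available. Local cost is |x − y| for
  univariate series and the Euclidean row distance for dependent bivariate
  series (the two dimensions share one alignment). Series are compared in
  raw percent units: z-normalisation would erase exactly the amplitude
  differences that distinguish a volatile from a stable patient. DTW is not
  a metric; no triangle inequality is claimed, and none is needed.
* **Distinctiveness** is the mean of a patient's DTW distances to all other
  patients; its variance across patients ranks the candidate target-coverage
  measures (GTV/CTV/PTV D95, computed on univariate series), the lowest
  variance winning, ties broken by that fixed order and flagged.
* **Clustering** follows the literal published construction: k-means
  (Lloyd, k-means++ seeding, best of 50 restarts, deterministic given a
  seed) on the *rows of the DTW distance matrix* as feature vectors, for the
  paired (representative D95, OAR dose) bivariate series. The scree of total
  within-cluster sum of squares over k = 1..8 is monotonised and the elbow
  taken as the interior k maximising the second difference
  WSS(k−1) − 2 WSS(k) + WSS(k+1) (smallest k on ties, flagged); the cluster
  count actually used is k_elbow + 1, a deliberate over-segmentation for a
  small cohort, and clusters with fewer than 10 members are excluded as
  outlier cases. A scree with no decrease at all (identical patients) is
  flagged degenerate and treated as k_elbow = 1, so k_used = 2. k_max = 8
  gives the scree room to bend: with 40 patients and a minimum retained size
  of 10, more than 4 retained clusters is impossible anyway.

With variance-only separation between the planted clusters, the minority
cluster has no centroid of its own in row space, and at k_elbow + 1 the
third centroid may either capture a few extreme patients (leaving two
retained clusters, the typical outcome at the default configuration) or
bisect the minority (leaving one). The default outlier-point structure makes
genuinely extreme patients common enough that the two-retained-clusters
outcome is the modal one, but it is not guaranteed for every seed — an
intrinsic property of k-means on variance-separated groups, worth keeping in
mind when interpreting retained-cluster counts on real cohorts.

## Trajectory summaries

Per retained cluster and fraction: n, mean deviation, and mean ± 1.96·SD/√n
(sample SD, n − 1 denominator). The normal z is used even for clusters near
the 10-member minimum, honouring the published convention; a t quantile
would widen the band by ~12 % at n = 10. Fractions with fewer than two
contributors are masked. Bands are across patients within a cluster, not
bootstrap bands.

## What the tests show — and what they cannot

Oracle suites pin the numerics: DTW equals exhaustive warping-path
enumeration for short series, k-means equals exhaustive bipartition search
for small cohorts, Cook's distance equals the leave-one-out definition by
brute-force refitting, and OLS matches the normal equations to 1e-10.
Stochastic suites check calibration recovery (seed-averaged mixed-model
slopes within the published CIs; ~92 % CI coverage of the generating slope
over 200 cohorts; planted-cluster recovery with ARI ≥ 0.8 in ≥ 90 % of
cohorts under 3:1 noise separation). All of this validates the pipeline
*under the generator's assumptions* — linear trends, Gaussian AR(1) noise,
independent parameters. Real cohorts deviate from these in known ways
(nonlinear early anatomical change, correlated parameters, occasional
replanning); passing tests show the machinery is correct, not that real data
will be as well-behaved.

Problem sizes throughout (40 × 30 cohorts, 20–200 seed replicates) were
chosen so each check exercises the full pipeline at the study's native scale.
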