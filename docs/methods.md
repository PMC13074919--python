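# Methods

`eoniche` implements three linked analyses for hothouse-interval (Early
Eocene) floras, plus a synthetic-data layer that gives every stage a
recoverable ground truth.

## 1. Rarefied richness and pairwise bootstrap inference

**Model.** Richness is standardized across assemblages by rarefaction to a
common number of individuals. For an assemblage with taxon counts
`N_1..N_S` (total `N`), the expected richness in a uniform random subsample
of `m` individuals is the hypergeometric expectation

    S(m) = S_obs − Σ_i C(N − N_i, m) / C(N, m),

evaluated in log-gamma arithmetic so `N ≈ 10^4` does not overflow.
Extrapolation beyond `N` uses the Chao-type unseen-species estimate
`f̂0 = ((N−1)/N) f1²/(2 f2)` (bias-corrected `((N−1)/N) f1(f1−1)/2` when
`f2 = 0`) and `S(N+m*) = S_obs + f̂0 [1 − (1 − f1/(N f̂0 + f1))^{m*}]`.

**Standardization rule.** Assemblages with `N < max(1000, 0.5 ·
N_2nd-smallest)` are excluded (the second-smallest `N` is taken over all
inputs); `m0` is the minimum `N` among those retained, so no test requires
extrapolation.

**Inference.** Each assemblage is resampled `B = 200` times multinomially
with `N` fixed; `S*(m0)` is recomputed exactly per replicate (no curve-grid
interpolation, removing a source of discretization noise). For a pair,
`Δ = S_A(m0) − S_B(m0)`, the CI is the 2.5–97.5 percentile interval of
`Δ*`, and the two-sided p-value is `p = 2·min(#{Δ* ≤ 0}, #{Δ* ≥ 0})/B`,
clipped to [0, 1]. When no replicate crosses zero, `p` is censored below
`1/B` and reported as `"<1/B"`. Bonferroni uses `K` = number of tests
actually run after exclusion. The CI is the plain percentile interval, not
BCa; nothing finer is claimed by the procedure being mirrored.

**Calibration.** Under the null (two assemblages drawn from one
species-abundance distribution, `N = 3000`, `m0 = 1000`, `B = 200`) the
test's empirical type-I error over seed replicates is ≈ 5%, comfortably
below the 10% bound the acceptance suite enforces. The bootstrap is a
plug-in approximation — it resamples around the observed composition, not
around the truth — which makes it mildly conservative here.

## 2. Climate fields: harmonization, bioclim variables, classification

**Regridding.** Fields on regular lon/lat grids are moved to a common grid
by bilinear interpolation (scipy `RegularGridInterpolator`), with cyclic
padding in longitude so interpolation crosses the dateline, and NaN outside
the source latitude coverage. Bilinear interpolation is exact for affine
functions of (lon, lat) and the identity on aligned grids; both properties
are tested to 1e−9.

**Bioclim variables.** Twenty-two summaries (Var1..Var22) are derived from
12-band monthly temperature (K), precipitation and evaporation (mm/month),
and orography (m): annual means/sums, fixed-calendar JJA and DJF windows,
warmest/coolest and wettest/driest months, and hydric balance defined as
evaporation minus precipitation (annual, seasonal, and at the
warmest/coolest-month extremes: Var21 = Var19 − Var17, Var22 = Var20 −
Var18). Temperatures stay in kelvin throughout; Var2 is the monthly range
×10. DJF uses months 12, 1, 2 of the same 12-band stack (the stack carries
a climatology, not a time series, so the December of "the previous year" is
the same December). Missing months poison every derived layer of that cell.

**Köppen–Geiger.** The classifier follows the widely used
threshold-ruleset translation (Beck-style): arid (B) classes are assigned
first from the aridity threshold (2·MAT, +14 or +28 depending on whether
precipitation concentrates in the cooler or warmer half-year; half-years
are AMJJAS vs ONDJFM, hemisphere-aware); then tropical (A: coldest month
≥ 18 °C, split Af/Am/Aw by driest-month rules), polar (E: hottest ≤ 10 °C,
ET/EF at 0 °C), temperate (C: coldest in (0, 18] °C) and continental (D:
coldest ≤ 0 °C) with s/w/f precipitation suffixes and a/b/c(/d) summer-heat
suffixes (a: hottest ≥ 22 °C; b: ≥ 4 months above 10 °C; d: coldest <
−38 °C). This yields a complete partition: every cell with 12 finite months
receives exactly one of 30 classes. Temperatures in kelvin are detected
(mean > 150) and converted internally, so classifying K or °C inputs is
identical.

**Nix thermal regimes.** Megathermal: MAT ≥ 22 °C and MAP > 549 mm;
mesothermal: 14 ≤ MAT < 22 °C and MAP > 549 mm; microthermal: MAT < 14 °C
and 719 ≤ MAP ≤ 3000 mm; otherwise unclassified. The boundaries are
half-open (22 belongs to megathermal, 14 to mesothermal) so the regimes are
disjoint — the printed "≥ 14–22" ranges do not specify this, and a
disjoint partition is the only self-consistent reading.

**Site extraction** uses the containing-cell (nearest-center) rule with
ties to the smaller index; values are extracted after regridding, so
bilinear re-interpolation at sites would double-smooth.

## 3. Presence-background niche models

**Workflow.** Occurrences are thinned to one per predictor-grid cell
(first point in a deterministic lon/lat sort — resolution-matched and
parameter-free). The calibration region is either a great-circle buffer
(haversine, Earth radius 6371 km; default 450 km) around thinned
occurrences or the bounding box of the points. Background (default 15,000
points) is sampled uniformly over region cells, without replacement when
the region is large enough, otherwise with replacement and a warning.
Predictors are screened by dropping near-constants and then greedily
resolving Spearman |r| ≥ 0.80 pairs (computed on 10,000 sampled cells),
removing the member of the worst pair with the larger mean absolute
correlation to the rest — the standard greedy collinearity filter.

**Features.** Raw predictors are min-max scaled to [0, 1] from background
statistics; feature classes are linear (l), quadratic (q), pairwise
products (p), and hinge (h: forward and reverse ramps at 20 knots placed at
evenly spaced background quantiles). The hinge count and knot rule are
fixed for reproducibility.

**Fit.** Coefficients maximize the penalized presence-background
log-likelihood of an exponential (Gibbs) model normalized over the
background sample,

    mean_presence(η) − log mean_background(e^η) − Σ_j λ_j |β_j|,

solved by FISTA (proximal gradient with backtracking; the problem is
convex, so the solver is deterministic). Per-feature penalties are
`λ_j = reg · c_class / √n_presences` with `c` = 0.1 (linear, quadratic),
0.2 (product), 0.5 (hinge); this schedule preserves the qualitative
structure of maxent-family defaults (hinge penalized hardest, penalties
shrinking with presence sample size, everything scaled by the
regularization multiplier) without claiming numeric parity with any
published tool. Suitability is reported on the cloglog scale,
`1 − exp(−e^H · raw(x))`, where `raw` is the background-normalized density
and `H` its entropy over background points.

**Tuning and evaluation.** A grid over feature-class sets × regularization
multipliers (1–3, step 0.5) is scored by k-fold CV (default k = 5, plain
random folds — spatial blocking is out of scope). Selection is
lexicographic: candidates within ΔAUC ≤ 0.005 of the best mean AUC, then
within ΔOR_P10 ≤ 0.01 of the lowest omission, then the simplest feature
set (l < lq < lh < lqh < lqph), then the smallest multiplier. The margins
make "favor simpler sets when differences are negligible" operational. AUC
is the rank statistic with ties counted 1/2; OR_P10 is the fraction of test
presences scoring strictly below the 10th percentile (linear interpolation)
of training-presence suitability, hence a multiple of 1/n_test.
A minimum of 8 presences is required to fit (fossil calibrations run with
11). Bootstrap ensembles refit on presence resamples with background held
constant (default 10 replicates) and report the cell-wise mean raster and
mean P10. Permutation importance shuffles one predictor across evaluation
rows, takes the AUC drop (clipped at 0, averaged over 2 shuffles), and
normalizes to sum 100.

## 4. Synthetic data: what it emulates and what it does not

* **Assemblages** draw a species pool's relative abundances once per spec
  (lognormal on log-abundance, log-series, or uniform) and then sample
  individuals multinomially — the same mechanism the bootstrap assumes. The
  source assemblages' true abundance distributions are unknown, so the
  generator's distributions are free choices, not estimates.
* **Climate grids** combine a linear decline of mean temperature with
  |latitude| (default 301 K at the equator, 0.35 K/deg — a weak-gradient
  hothouse sketch), a cosine seasonal cycle (default amplitude 6 K) peaking
  in July north of the equator and January south of it, a cos² latitudinal
  precipitation profile (150 → 40 mm/month), evaporation as a linear
  function of monthly temperature plus noise (so hydric-balance variables
  are non-degenerate), and a smooth deterministic orography ridge. The
  3-month average of the cosine at its extremes is (1 + 2cos 30°)/3 ≈
  0.9107, so the generator's DJF−JJA contrast is 2·A·0.9107 (≈ 9.11 K for
  A = 5), which is what tests assert.
* **Occurrences** are sampled cell-wise with replacement in proportion to a
  known logistic or gaussian response to one bioclim variable; duplicates
  are intended (thinning removes them).
* None of this mimics real GCM spatial structure, orographic rainfall,
  land/sea masks, or real *Nothofagus* biogeography. Passing tests
  demonstrate statistical correctness of the machinery, not fidelity of any
  particular paleo-reconstruction.

**Recovery experiment.** The standing niche-recovery benchmark generates
200 presences from a logistic response to mean annual temperature (Var1)
centered at the driver's 85th percentile with slope 2 K⁻¹ (concentrating
presences in the warm ~15% of the grid — a response centered mid-domain
leaves half the grid near suitability 1 and caps attainable AUC near 0.75),
adds three independent standard-normal noise predictors, and fits an
`lh` model against 15,000 background points on a 3° grid. Holdout AUC runs
≈ 0.92, the driver is rank-1 by permutation importance in ~100% of seeds,
and training omission at P10 sits within 1/n of 0.10 by construction of
the threshold.

## 5. Numerical and engineering choices

* Log-gamma binomial coefficients; terms with `C(N−N_i, m)` undefined
  (N−N_i < m) contribute zero absence probability.
* FISTA: 500 iterations max, relative objective tolerance 1e−7, step-size
  backtracking with regrowth; soft-threshold proximal step with per-feature
  weights.
* Bootstrap p-values are clipped to [0, 1]; censored values keep a numeric
  stand-in of 1/B alongside the "<1/B" label so tables sort sensibly.
* One master seed fans out to per-stage seeds via `SeedSequence.spawn`, so
  stages are independently reproducible; every run writes a manifest with
  effective settings, stage seeds, and input checksums.
* Raster I/O is NetCDF (CF-style lat/lon) via xarray's scipy backend;
  categorical maps are written as integer codes with the class table in an
  attribute. Test problem sizes (3–6° grids, 30–100 seed replicates,
  4000–15,000 background points) were chosen so the full suite and the
  acceptance script each complete in minutes on one CPU.

## Known limitations

* The Köppen implementation fixes one of several published variants
  (Tcold = 0 °C for the C/D split, B with priority over E); classifications
  near those thresholds are variant-dependent.
* The maxnet-style penalty schedule is this package's own; coefficient-level
  parity with published tool output is not claimed (the loss family and
  cloglog transform are the same).
* The bounding-box calibration region ignores longitude wrap; fossil
  bounding boxes spanning the dateline should be split by the caller.
* Plain random CV folds overestimate transferability under strong spatial
  autocorrelation; spatial blocking is deliberately out of scope.
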