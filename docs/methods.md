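# Methods

This note documents the statistical model behind `ecotrend`, the choices
made where the procedure was genuinely open, and what the synthetic test
bed does and does not demonstrate about real satellite records.

## Problem setting

The package detects statistically significant, spatially coherent monotonic
change in monthly gridded records of soil moisture (SM, m³·m⁻³) and
vegetation optical depth (VOD, unitless), with precipitation (mm/month) and
NDVI as auxiliary covariates, and summarises joint (SM, VOD) change clusters
together with fractional land-cover change. Typical inputs are a decade of
monthly maps on a ~25-km grid.

## Per-cell trend test

For one cell and one quantile level q ∈ {0.1, 0.25, 0.5, 0.75, 0.9}:

1. **Annual quantile series.** y_t = empirical q-quantile (linear
   interpolation between order statistics, the numpy default) of year t's
   monthly values. Using quantiles of the annual distribution rather than
   means makes the test sensitive to changes in different parts of the
   distribution (dry/wet tails vs the median) and removes the seasonal
   phase. Years with more than half their months missing are dropped; cells
   with fewer than 3 usable years (4 for testing) are masked.
2. **AR(1) pre-whitening.** r₁ is the plain sample lag-1 autocorrelation of
   the annual series (0 for a constant series) and the residual series is
   y′_t = y_t − r₁·y_{t−1}, t = 2..n. Annual geophysical series are serially
   correlated, and the Mann–Kendall test assumes exchangeability; without
   this step the false-positive rate roughly quadruples at the scales we
   simulate (the type-I acceptance test measures both rates).
3. **Mann–Kendall test** on y′: S = Σ_{i<j} sign(y′_j − y′_i),
   Var(S) = [n(n−1)(2n+5) − Σ_g t_g(t_g−1)(2t_g+5)]/18 over tie groups g,
   Z with the classical continuity correction ((S∓1)/√Var(S); Z = 0 for
   |S| ≤ 1), two-sided normal p-value.
4. **Sen's slope** (median of pairwise slopes, units/yr) on the
   *un-whitened* annual series — pre-whitening rescales magnitudes and
   would bias the slope. OLS is available as an alternative estimator
   (`slope_estimator="ols"`); Sen is the default because it is the standard
   robust companion of MK. Relative trends are 100·slope/mean(y) in %/yr.

Design points that were open and are fixed here: r₁ is estimated on the
annual (tested) series, not the monthly one; the pre-whitened series drops
its first element (the residual is undefined at t = 1); trend-free
pre-whitening (detrend before estimating r₁) is deliberately not the
default, matching the minimal procedure the package implements.

## Field significance

Testing thousands of cells guarantees spurious "significant" cells, and
spatial correlation clumps them into patches that imitate real signal. The
correction builds the null distribution of the *maximum connected patch
size* (8-connectivity by default; 4 available): each of n_perm (≥ 100,
default 500, 200 in the shipped configurations) permutations draws ONE
shuffle of the year labels and applies it identically at every cell, so each
year's spatial field stays intact and the spatial correlation is preserved;
the whole per-cell chain (including re-estimated pre-whitening) is re-run
and the largest patch of p < α cells recorded. Observed patches are kept iff
their size strictly exceeds the 0.95 null quantile. This controls the
family-wise probability of reporting any spurious cluster at ≈ 5%; the test
suite verifies the realised rate on pure-noise scenarios and that an
*independent* per-cell shuffle understates the null (which is why the shared
shuffle is required).

## Merging and bivariate clustering

Per variable, the five quantile-wise retained-cluster maps are merged: a
cell changes if any quantile retains it; its sign is the majority sign over
its significant quantiles (an exact tie is conservatively "no change"); its
slope is the median Sen slope over significant quantiles (over all
quantiles for unflagged cells, so auxiliary sign/magnitude information is
always defined).

Cells significant in SM and/or VOD are then placed in the bivariate
trend-sign plane (the non-significant variable contributes the sign of its
slope layer):

* (+, +) splits into **A** vs **D** by the precipitation relative trend
  (threshold 1 %/yr by default): A-type change is rainfall-driven, D-type
  is not.
* (−, −) splits into **B** (milder) vs **E** (stronger) by the joint
  relative-slope magnitude √(rel_SM² + rel_VOD²). The default threshold is
  a deterministic two-class variance-minimising split (Otsu-style) with a
  guard — if the two candidate class centres are closer than one pooled
  standard deviation the population is treated as homogeneous (all B). A
  fixed threshold can be passed instead. A percentile split was rejected
  because it hard-codes the relative abundance of the two groups.
* (−, +) is **C** (the soil-drying/greening pattern), (+, −) is **X**
  (kept for completeness; not observed in the decade-scale record this
  emulates).

Each category is decomposed into connected components; components smaller
than `min_area_cells` (default 20) are dropped. Cluster areas use
cos(latitude)-weighted cell areas (cell_km² · cos φ). Separability of a
labelling is scored as the mean silhouette coefficient in z-scored feature
space.

## Land cover

Fine categorical maps (11 broad plant-functional-type classes) are
aggregated to the analysis grid as per-class area fractions (the fraction of
fine pixels per coarse cell); two epochs are differenced per class, and
per-cluster net change tables are Σ Δfraction × cell area (km²). Net change
is reported, not gross turnover; per-cell Δ sums to zero over classes by
construction. The coarse/fine ratio is a free integer so tests stay small;
a 500 m → 30 km setup corresponds to a factor of 60.

## Synthetic scenarios

`generate_cube` produces base + 12-month sinusoid + spatially smoothed
AR(1) noise + linear ramps inside disjoint region masks. Noise is AR(1) per
cell (monthly φ = 0.5 by default), then each monthly slice is smoothed with
a normalised Gaussian kernel (width `spatial_corr_cells`, circular
boundary — the slice mean is preserved to machine precision); this gives
independent temporal and spatial correlation knobs. Ramps are not smoothed,
so region edges are sharp and recovery scores are attributable to the
testing chain. SM is clipped to [0, 1], NDVI to [−1, 1], VOD and
precipitation to ≥ 0.

The five-region scenario uses a 48×48 grid (25-km cells), 10 years, and
slope magnitudes anchored to decade-scale rates reported for the real-world
counterparts of the five patterns (e.g. SM −0.0053 m³·m⁻³/yr in the
B-type region; VOD ≈ +4 %/yr in C; the strongest joint decline in E;
a large VOD rise with modest SM change in D). A and D are separable both by
the precipitation trend (A: +3 %/yr, D: 0) and, more weakly, in (SM, VOD)
slope space. Noise defaults (SM 0.012, VOD 0.015, NDVI 0.02, precip
10 mm/month innovation s.d.) are chosen as plausible retrieval-noise scales;
the real products' noise magnitudes and spatial correlation are not
published, so these are testability choices, not climatological claims.

What the scenario does **not** emulate: realistic seasonal phenology shapes,
retrieval-error heterogeneity (RFI, dense-canopy SM degradation), coastlines
and missing-data structure, or non-linear change (droughts, step changes).
Passing the recovery tests therefore shows the chain is correct and
calibrated under its own assumptions — not that the real record's clusters
are certain to be recovered at these rates.

## Numerical choices and problem sizes

* Quantiles: linear interpolation between order statistics everywhere
  (tables depend on this choice).
* MK variance uses exact tie groups; S and Var(S) are validated against an
  exhaustive O(n²) oracle, exactly, on tied series.
* Retention uses a strict inequality against the null quantile
  (conservative for the discrete cluster-size distribution).
* Deterministic seeding throughout via `numpy.random.SeedSequence` spawning;
  identical config + seed give bitwise-identical scenarios and manifests.
* Shipped statistical checks use: 200 random series for oracle equivalence;
  5000 AR(1) series (n = 30, φ = 0.5) for type-I rates; 200 pure-noise
  40×40×10-yr scenarios with 200 permutations for the family-wise rate;
  the 48×48 five-region scenario with 200 permutations per quantile and
  variable for recovery; 10 scenario seeds for the separability ordering.

## Known limitations

* The normal approximation to S is used for n ≥ 3 after pre-whitening;
  below n ≈ 8 annual values the test is conservative and weak — a decade of
  data is near the practical minimum, as in the record this emulates.
* Pre-whitening with an estimated r₁ slightly reduces power against true
  trends (part of the trend leaks into r₁); trend-free pre-whitening would
  recover some power at the cost of a more complex null.
* The A/D precipitation threshold and the B/E magnitude split are
  configuration, not estimates; with real data they should be set from the
  bivariate distributions (the auto split helps only when the (−,−)
  population is genuinely bimodal).
* Cluster areas assume a regular lat/lon grid; equal-area grids should
  supply their own per-row areas.
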