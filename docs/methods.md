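# Methods

`vegdrivers` implements a driver-attribution analysis for vegetation
change over a set of administrative units (cities), of the kind used to
ask why leaf area index (LAI) rose across a river basin over four
decades: which natural, social, economic and policy factors drove the
*temporal* change at each place, and which control the *spatial*
pattern.

## The varying-coefficient regression (GTWR)

The temporal-attribution stage fits, at every unit-year record i,

y_i = β₀(u_i, v_i, t_i) + Σ_k β_k(u_i, v_i, t_i)·x_ik + ε_i,

a linear model whose coefficients are free to vary over space (u, v) and
time (t).  Estimation is local weighted least squares: record i's
coefficients solve (Xᵀ W_i X) β = Xᵀ W_i y with diagonal weights

w_ij = K(d_ij / b),  d_ij² = (u_i−u_j)² + (v_i−v_j)² + τ (t_i−t_j)²,

K Gaussian by default (bisquare optional), b the bandwidth and τ the
space/time equivalence ratio in km²/yr².  The focal record is included
in its own fit, standard practice for geographically weighted
regression.

Assumptions worth stating: the response is linear in the drivers at
every location (only the coefficients vary); coefficient surfaces are
smooth at the kernel's scale; errors are independent with constant
variance.  None of these are tested by the fit itself.

### Bandwidth and τ selection

* **Criterion** — leave-one-out cross-validation (the self-weight is
  zeroed, algebraically identical to deleting the record and refitting);
  AICc with the hat-matrix trace is available as an alternative.
* **Search** — a candidate grid (default: 2–80 % of the spatiotemporal
  data diameter), then golden-section refinement between the grid
  neighbours of the argmin; ties prefer the smaller bandwidth.
* **τ** — selected on the same criterion over a geometric outer grid
  {1, 4, 16, 64, 256} km²/yr².  With coordinates in kilometres over a
  ~1000 km domain and time in years over four decades, the right
  equivalence is a priori unknown to within orders of magnitude; a
  near-unity τ makes every temporal neighbour closer than the nearest
  spatial neighbour and degenerates the fit to per-unit time-series
  regression, so the grid must reach values where one year trades
  against tens of kilometres.  On the default synthetic panel the
  criterion selects τ in the upper part of this grid.
* **Degenerate systems** — a local cross-product matrix that is singular
  within tolerance is refit with a trace-scaled ridge (1e-8·tr(A)/p) and
  the record flagged; flagged records are excluded from summaries, and a
  fit with more than 10 % flagged records aborts with advice to enlarge
  the bandwidth.  Records whose non-self weight mass falls below a small
  floor (1e-3) are flagged for the same reason.

All-records fits are assembled as one matrix product over flattened
outer products and solved with batched LAPACK, which keeps a 2000-record
fit under a second; results are bit-deterministic for a given panel and
configuration.

### Coefficient products

Per-year distributions of each β̂_k across units (box-plot view),
per-unit time means (map view), and the **dominant factor** per unit:
the largest |time-mean standardized coefficient|, signed by its
direction.  Exact ties break lexicographically by factor name and are
flagged.  Alternative dominance rules (final-year coefficient) sit
behind a flag; the time-mean is the default because it is stable over
the fitted period.  Dominance comparisons require standardized
predictors — the pipeline z-scores all drivers (population sd) before
fitting and stores the transform for exact inversion.

## The geographical-detector q-statistic

For the spatial-attribution stage each candidate driver is discretised
into L strata and scored by

q = 1 − SSW/SST,  SSW = Σ_h N_h σ_h²,  SST = N σ²,

with **population** variances throughout, so SSW + Σ_h N_h(ȳ_h−ȳ)² =
SST holds exactly and q ∈ [0, 1].  With sample variances the identity
fails for unequal stratum sizes, which is why the population form is
non-negotiable here.

* **Discretisation** — quantile breaks with L = 5 by default (ties to
  the lower stratum, empty strata collapsed); equal-interval and exact
  natural breaks (minimum within-class sum of squares by dynamic
  programming over the sorted values) are available.  A constant driver
  collapses to one stratum and q = 0.
* **Significance** — a seeded permutation test by default: B = 999
  relabelings, p = (1 + #{q* ≥ q}) / (B + 1).  This is distribution-free
  and mildly conservative (its rejection rate at nominal 0.05 is ≈0.049).
  The noncentral-F reference used by the canonical geodetector software
  is available for parity.
* **Missing cells** — a factor unavailable in a year (the policy ratio
  before the programme window) is carried as missing, never as 0.

Dimension averages are unweighted means of available q over the factors
of each dimension (natural {MT, MP, MD, MS}, social {PD, EPR, PI, FR,
GY}, economic {PG, PC, IS, IOR, IR}, policy {GRGR}); a dimension with no
available factor in a year stays missing.

## Trend products

Per-series slope is closed-form OLS, Σ(t−t̄)(y−ȳ)/Σ(t−t̄)², with a
two-sided t-test on n−2 degrees of freedom; Theil–Sen with a
Mann–Kendall p-value is available for robustness checks but is not the
default (the t-test matches the "p < 0.05" significance convention of
this product line).  Classification is total: significant/non-significant
increase/decrease by the sign of the slope and p against α = 0.05, an
exact-zero slope its own FLAT class (mergeable into non-significant
increase by flag), and series with fewer than three finite points
NO_DATA, excluded from area fractions.  Segment rates around a policy
breakpoint fit the two sides independently, with the split year included
in **both** segments (the 1980–2000 / 2000–2019 convention).

## Indicators and the policy ratio

The socio-economic indicators are exact ratios of yearbook fields (per
capita or per unit area); records with a zero denominator get a missing
value for that indicator and a log entry.  Monetary fields are used
nominal — no deflator is applied.

The Grain-for-Green ratio (GRGR) is derived from annual land-use class
grids: cells cropland in *every* baseline year (1980–2000) are permanent
cropland; the numerator counts permanent-cropland cells *ever* converted
to forest/shrubland/grassland in a programme-window year (2001–2020) up
to the target year, so the series is monotone nondecreasing and
reversion never decrements.  The denominator defaults to the union of
cropland cells over the baseline years ("total cropland area" read as
baseline cropland) and can be switched to the permanent mask itself.
Cells belong to the zone containing their centre.  Zones with zero
cropland yield a missing ratio with a log entry.

## Collinearity screen

VIF_j = 1/(1−R_j²) from regressing driver j on all others (with
intercept) over the pooled panel; exact collinearity is reported as +∞
rather than raised.  Screening is single-pass — every driver above the
threshold (default 7.5) is removed at once — matching the convention of
removing a named set of collinear covariates together; an iterative
drop-the-worst mode is available.

## The synthetic generators

The generators produce the study conditions, not miniatures of them:

* **Panel** — 50 units × 40 years (1980–2019) on a jittered regular grid
  (jitter sd 5 % of spacing) over a 1000×800 km planar domain; affine
  coefficient surfaces β_k = a + b·u + c·v + d·(t−t₀) with per-factor
  parameters chosen so each field spans roughly ±0.3–0.5 over the domain
  and ±0.2–0.5 over the period; iid standard-normal drivers (pairwise
  correlation configurable); Gaussian noise sd 0.1 response units.  The
  nine retained factors carry distinct surfaces; the four screened-out
  covariates are noisy sums of two retained factors each (noise sd 0.45,
  giving them VIF ≈ 11 while keeping their parents near 5–6).  External
  values (e.g. a land-use-derived GRGR) can replace any driver's draws
  before the response is generated, so the response still follows the
  model exactly.
* **Trend raster** — cells are labelled decreasing / weakly increasing /
  strongly increasing with configured fractions (defaults 0.43 / 0.46 /
  0.11); slopes 0.02, 0.004 and −0.004 per year against noise sd 0.1
  over 40 years make the strong cells detectable at α = 0.05 with high
  probability and the sign of every cell recoverable with ≈97–99 %
  probability.  Note the *significant* fraction is not cell-wise
  recoverable by construction: a cell that should trend upward but stay
  non-significant needs slope/se ≳ 2.5 for its sign and < 2 for its
  p-value simultaneously, which no noise level satisfies.  Only the
  increasing-area fraction is treated as a recoverable target.
* **Land use** — a constant baseline map (cropland fraction 0.4) through
  2000, then conversion of permanent-cropland cells to
  forest/shrubland/grassland in a fixed random order following a
  cumulative schedule (default: 2 % by 2005, 18 % by 2010, plateau, 20 %
  by 2020, echoing the observed ramp-then-plateau implementation
  pattern).  Converted cells never revert.
* **Raw statistics** — yearbook-style magnitudes (populations 10⁵–10⁷,
  growing per-capita GDP, grain yields 1.6–9 t/ha, investment above GDP
  so the input–output ratio sits in ~0.35–0.9) for exercising the
  indicator formulas; no spatial structure is claimed.

What the generators do **not** emulate: spatial autocorrelation of real
LAI fields, climate reanalysis structure, realistic administrative
geometries (zones are rectangles), or coupling between the raster,
land-use and panel worlds beyond the GRGR injection.  Passing tests
therefore demonstrate correctness of the estimators under the stated
model, not fidelity to the real basin's data.

One global seed feeds named substreams (panel / raster / landuse /
zones / rawstats), so any product regenerates independently and
bit-identically.

## Problem sizes and numerical checks

The test and acceptance runs use: the full 50×40 panel for GTWR limit
checks (global-OLS reduction at 10⁶× the data diameter, tolerance 1e-8;
exact fit of a zero-noise global model at 0.1–10× the diameter,
tolerance 1e-6) and recovery (per-factor Pearson r between fitted and
true coefficient fields, noise sd ∈ {0.5, 0.1, 0.02}); 1000 random
instances (N ≤ 50, L ≤ 6) for the q-statistic against brute-force
decomposition at 1e-12; 200 null replicates at N = 200, B = 999 for
permutation calibration; a 100×100 raster for trend-fraction recovery
(±2 percentage points); and a reduced 20-unit pipeline run, twice, for
checksum-level determinism.

## Known limitations

* The local model is linear; threshold or saturating driver effects are
  out of scope.
* LOOCV targets prediction error, not coefficient error; on
  heterogeneous-variance data it can select bandwidths that are
  too small for stable coefficient maps (the flagged-record guard
  catches the extreme cases only).
* The q-statistic depends on the discretisation; with the stratification
  scheme unknown, published q matrices are reproducible only up to that
  choice.
* Permutation p-values are lower-bounded at 1/(B+1); B = 999 cannot
  certify p < 0.001.
* The equirectangular lon/lat→km conversion is adequate for mid-latitude
  domains of a few thousand km, not for polar or continental-scale work.
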