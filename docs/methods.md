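# Methods

This note records the statistical model the package implements, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish.

## Thermal stress metrics

Daily SST per island buffer is ingested as a contiguous series; gaps of up
to 3 days are linearly interpolated, longer gaps are rejected rather than
guessed.  The MMM climatology pools daily values by calendar month across
the configured climatology years (default: the full record excluding the
final, event, year) and takes the warmest monthly mean; leap days count
toward February.  HotSpots are the positive part of SST − MMM.  DHW sums
HotSpots over a trailing 84-day window and divides by 7; following the
Coral Reef Watch v3.1 convention, only HotSpots ≥ 1 °C accumulate.  The
cutoff is exposed as `min_accumulating_hotspot` because product
definitions differ across versions; setting it to 0 reproduces the older
all-HotSpots accumulation.  The first 83 days are flagged as spin-up.  The
incremental cumulative-sum implementation is tested against a naive
window summation to 1e-9, and both DHW and HotSpots are invariant under a
common shift of SST and MMM.

## Susceptibility score

BS = (Σ P_st·S_t)/P_s is applied exactly as written: live cover that
carries no score dilutes the score toward zero.  The alternative —
renormalising by scored cover only — was rejected because it changes the
estimand (mean susceptibility of *scored* cover, not of the community).
Species missing from the score table fall back to their genus score when
one exists, with a log line per use.  Synonym maps are resolved to their
transitive closure (cycles rejected); merged taxa sum their covers, and
their percent-bleached values merge as the cover-weighted mean so bleached
area is conserved.  BS is reported to 3 decimals in written outputs but
carried at full precision internally; tests compare at 1e-12.

## Clustering, cells, weights

* **Complete linkage at 1 km** treats "within 1 km of one another" as a
  bound on the cluster diameter.  Single linkage would allow chains whose
  ends are much farther apart than 1 km.  Distances are haversine with
  Earth radius 6371.0088 km (the IUGG mean radius).  Clusters are
  relabelled by first appearance, making the assignment deterministic and
  permutation-stable up to relabelling.
* Depth bins are (0–6], (6–18], (18–30] m with 0 m in shallow; depths
  outside [0, 30] m are rejected at the door.
* Cell SE = sample SD / √n, undefined at n = 1.  Weights are 1/SE, capped
  at the 95th percentile of raw weights and divided by it, so weights lie
  in (0, 1] with the cap binding at least once.  Cells with undefined or
  zero SE get the 5th-percentile **raw** weight before scaling — the
  substitution happens on the raw scale because the scaled alternative
  would make the substituted value depend on the cap.  Percentiles use
  linear interpolation between order statistics; percentiles are pooled
  over the analysis set rather than computed per region.

## Covariates

Ocean-colour pixels are masked when more than 5 % of their footprint lies
at depths ≤ 30 m, evaluated by block-counting a co-registered bathymetry
grid at the same or an integer-factor finer resolution.  Point extraction
returns the containing pixel when valid; otherwise the search radius
expands to the nearest valid pixel and the mean of *all* valid pixels
within that radius is returned, so equidistant pixels average rather than
tie-break arbitrarily.  Default maximum radius is 8 km, reduced to 750 m
for wave action, which is only meaningful near shore.

Transforms are per-variable monotone maps from {identity, log1p, sqrt},
chosen data-driven (sample skewness > 1 and non-negative support → log1p)
with explicit overrides taking precedence; centring and scaling use
unweighted moments (mean, SD with ddof = 1) over the analysis cells.  The
fitted `TransformRegistry` is serialised beside the driver matrix so
predictions can be mapped between natural and standardized scales.  Deep
(> 18 m) cells are excluded from the drivers analysis; cells with any
missing driver are dropped with a per-variable reason, and a warning fires
below 30 surviving cells.

## Drivers model and selection

The response is √(% bleached) per cell, weighted by the cell weights.
Candidate terms are all driver main effects plus the two interaction
families acute-DHW × driver and susceptibility × driver.  Backward
elimination removes, at each step, the single eligible term whose removal
most lowers BIC, stopping when no removal lowers it; ties break to the
alphabetically first term.  Marginality is enforced: a main effect is
ineligible while any of its interactions is retained — this mirrors
published best-fit tables in which a non-significant main effect stays in
the model alongside its significant interaction.  Pure backward search is
used (no re-addition step).  No island or zone fixed effects enter the
drivers model.

BIC is computed as n·log(RSS_w/n) + k·log(n) with RSS_w = Σ w_i e_i² and
k the coefficient count; weighted-likelihood BIC conventions differ, so
this one is fixed explicitly.  The effective sample size is the row count.

The spatial contrast is a weighted one-way ANOVA (F from nested weighted
RSS) with Tukey HSD computed on weighted group means using per-group
effective sample size Σw and the pooled weighted error variance — an
approximation appropriate when weights are inverse-variance-like.  The
temporal contrast for multi-zone regions is a random-intercept mixed model
(island as the grouping factor) with known observation weights, fitted by
maximum likelihood: the marginal covariance per group is
σ²·diag(1/w) + σ_b²·J, β is profiled out by GLS, and (log σ², log σ_b²)
are optimised by Nelder–Mead from multiple starts.  Likelihood-ratio χ²
statistics compare nested fixed-effect ML fits (interaction vs additive;
each main effect vs the additive model without it).  The variance can hit
the σ_b² → 0 boundary, where the fit coincides with WLS — this limit is
tested to 1e-4.  The two-island-group comparison uses a weighted two-way
ANOVA with Type-II style nested-model F tests.

## Scenarios

Perturbation analysis moves each driver in turn by ±1 SD (standardized
scale) with everything else at its mean; because predictors are centred,
every interaction vanishes at the baseline row and the baseline equals the
squared intercept exactly.  The management scenario keeps each cell's
*observed* driver values, overrides acute DHW with the analysis-set
quantile (default 0.95, computed over cells), shifts one manageable driver
at a time by −1 SD, and takes the largest predicted reduction as the best
action, with exact ties resolving alphabetically (a 1e-9 tolerance guards
against float jitter in tied predictions).  √-scale predictions below 0
clip to 0 and are logged, since they indicate extrapolation; percent
predictions clip at 100.  Partial-regression residual points are the
reduced-model residuals back-transformed with sign preserved
(sign(r)·r²), carrying their observation weights.

## Synthetic data

The generator emulates the three input families the analysis consumes.

* **Geometry.**  Hexagonal cluster layouts per zone (3.2 km spacing) with
  small jitter guarantee the contract the clustering stage assumes:
  same-cluster surveys < 1 km apart, distinct clusters > 2 km apart, so
  the 1-km complete-linkage cut recovers the generating clusters exactly.
  Infeasible requests (more clusters than the zone extent can hold) are
  rejected.
* **Drivers.**  Latent scores are correlated standard Gaussians
  (exchangeable correlation, default 0.2), winsorised at |z| = 3.5 and
  standardized empirically over the analysis cells; natural scales are
  monotone maps of these scores (log1p-style for right-skewed
  anthropogenic indices and heat-stress accumulations, affine otherwise)
  chosen so the covariate stage's transform-and-standardize path
  reproduces the generating design to machine precision.  Depth enters
  structurally from the cell's depth bin.
* **Response.**  Expected √-bleaching is exactly design · β.  Default
  coefficients use an intercept of 4 (≈ 16 % baseline bleaching) and
  moderate standardized effects of both signs with five two-way
  interactions, magnitudes kept small enough that latent means rarely
  reach the 0 or 100 % boundaries.  Cell noise is N(0, 0.5) on the √
  scale.  Replicate surveys draw from a Beta distribution on [0, 100]
  whose mean is the cell percent exactly and whose SD follows the
  proportion mean–variance relation (equal to `within_cluster_sd`,
  default 5 %, at 50 % bleaching).  A clipped-Gaussian replication model
  was tried first and rejected: its boundary bias at low-bleaching cells
  propagates through √(mean %) and systematically attenuates
  coefficients, defeating parameter-recovery testing.  Cells whose latent
  √ mean is clamped at 0 still carry a small boundary bias, visible as a
  slight downward shift absorbed mostly by the intercept.
* **Taxa.**  Five taxa with scores 1–5 (codes follow common Hawaiian
  reef-coral abbreviations; massive *Porites* least susceptible,
  *Pocillopora* most).  Each survey mixes the two taxa whose scores
  bracket the cell's target BS so the cover-weighted survey score equals
  the cell driver exactly; per-taxon bleaching is proportional to the
  taxon score, keeping taxon-level and survey-level bleaching mutually
  consistent.
* **SST.**  A sinusoidal seasonal cycle peaking in early September plus a
  configurable boxcar heatwave anomaly in the final year, with optional
  Gaussian noise; at least five years so a climatology is estimable.

What the generator does **not** emulate: real oceanographic structure
(advection, fronts, island wakes), observation error in taxon
identification, spatially autocorrelated residuals beyond the cluster
level, species interactions, or boundary-inflated (zero-heavy) bleaching
distributions.  Passing tests therefore demonstrate that the *pipeline*
is correct and unbiased under its stated model, not that the model is
adequate for any particular reef system.

## Problem sizes

Parameter-recovery checks use 20 seeds of ~312 analysis cells (4 islands
× 3 zones × 13 clusters × 2 depth bins), 3–6 surveys per cluster;
selection-behaviour checks use 50 seeds at n = 500 (null) and n = 300
(true-model) rows; the clustering contract uses 500 random layouts of up
to 25 surveys.  These sizes keep the whole suite and the acceptance
script fast while leaving the statistical conclusions stable across
seeds.

## Known limitations

* The weighted Tukey HSD uses effective sample sizes Σw in place of true
  replication; p-values are approximate.
* The mixed-model LRT relies on the usual χ² reference, which is
  conservative for variance components near the boundary; only fixed
  effects are tested here.
* The scenario machinery treats the fitted regression as a structural
  model; predicted "reductions" are associations, not causal effects, and
  no uncertainty is propagated onto the per-cell best action.
* The expanding-radius extraction computes great-circle distances to all
  pixel centres; for very large rasters a ring-indexed search would be
  faster, but grids at the scales used here make the direct computation
  cheap and exact.
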