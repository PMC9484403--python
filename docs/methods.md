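# Methods

This note documents the models, numerical choices and known limitations
of `coastsdm`. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Study design

The pipeline encodes a hindcast-validation design for coastal species
distribution models. One model per species is trained on a single
"present" window of climate (monthly normals averaged over 2013–2018)
using all cleaned occurrences, then projected — never refit — into two
past windows whose mangrove vs. salt-marsh dominance state is known from
independent observation (salt-marsh dominance 1984–1989, mangrove
dominance 2001–2006) and into future windows (2021–2040, 2041–2060,
2061–2080). All windows in the past and present span 6 years so that
each dominance phase of the oscillation is captured cleanly. The model
set is accepted ("validated") only if the hindcasts reproduce the
documented group-level ordering; only then are the future projections
interpreted.

## Spatial conventions

Rasters are regular WGS84 lat/lon lattices, row 0 northernmost, cells
addressed by center. Region and extent membership is by cell center with
inclusive bounds. The default study extent is longitude −120…−32,
latitude −36…36. ESRI ASCII grids are written with the
`ncols/nrows/xllcorner/yllcorner/cellsize/NODATA_value` header, values
row-major north-to-south at 6 significant digits (the documented
round-trip precision); GeoTIFF output is single-band float64 with
ModelPixelScale/ModelTiepoint/GDAL-nodata tags, which round-trips
exactly. Occurrence cleaning removes unparseable rows, non-finite
coordinates, the (0, 0) artifact common in digitized specimen data,
points outside the study extent, and duplicates; duplicates are exact
coordinate matches after rounding to 6 decimal places (~0.1 m — well
below any realistic georeferencing precision), a per-coordinate rather
than per-grid-cell rule. Species enter modeling only with ≥ 50 cleaned
occurrences. Cells with elevation strictly greater than 10 m are masked
to nodata before training and projection, restricting the analysis to
the low coastal fringe these species occupy.

## Bioclimatic variables

BIO1–BIO19 are computed per cell from the 12 monthly normals of tmin,
tmax (°C) and precipitation (mm). Conventions, chosen to match the
dominant `biovars` implementation and pinned by an independent
reference implementation in the test suite (agreement to 1e−9 on 1,000
random monthly vectors):

- monthly mean temperature is (tmax + tmin)/2;
- standard deviations use the sample (n−1) denominator (BIO4 = 100·sd of
  monthly means; BIO15 = 100·sd(prec)/(1 + mean(prec)), the +1 keeping
  arid cells finite);
- quarters are the 12 wrapping 3-consecutive-month windows
  (December→January wraps); wettest/driest quarters are ranked by
  precipitation sum, warmest/coldest by mean temperature; ties break to
  the earliest starting month, January first;
- BIO3 = 100·BIO2/BIO7 is set to nodata with a warning where the annual
  range BIO7 is zero;
- temperatures are plain °C (no ×10 integer encoding).

Correlation pruning computes pairwise Pearson r over jointly valid cells
and scans greedily in an explicit priority order: a variable is retained
iff |r| ≤ 0.7 against every already-retained variable, and every dropped
variable records its blocking partner and r. The default priority (BIO6,
BIO12, BIO2, BIO5, BIO15, BIO18, then the rest ascending) protects the
variables known to shape coastal range limits — cold extremes and
moisture — before generic summaries such as the annual mean; this
greedy-priority scheme is this package's design choice, since pruning
outcomes alone do not determine an algorithm. Zero-variance layers are
excluded with a warning.

## Maximum-entropy model

Features: variables are rescaled to [0, 1] by their training range
(presences and background jointly); linear, quadratic, pairwise product,
threshold (step indicators at 50 evenly spaced interior knots) and hinge
features (forward max(0,(x−k)/(1−k)) and reverse max(0,(k−x)/k) at a
shared 50-knot grid, omitting the degenerate end knot of each
direction). Nonlinear features of training-constant variables are
skipped with a warning.

Penalty: per-feature L1 weights follow the MaxEnt default schedule — a
feature-class base level interpolated by presence count m
(linear/quadratic/product: 1.0 → 0.05 as m goes 10 → 100; hinge: 0.5;
threshold: 2.0 → 1.0), multiplied by the feature's sample standard
deviation over the presences (floored at 1e−3), divided by √m, and
scaled by the user's regularization multiplier (tuning grid 0.5–4.0 in
steps of 0.5).

Optimization: monotone proximal-gradient ascent with soft thresholding
and backtracking line search on the concave smooth part; the step grows
back after accepted iterations. Convergence is declared when the
penalized objective changes by < 1e−6 (default) between iterations; the
trace records every objective value, so monotone ascent is a tested
invariant. On test fixtures the converged objective agrees with an
independent generic convex optimizer (L-BFGS-B on the positive/negative
coefficient split) to better than 1e−3, and with m = 2000 presences,
n = 10,000 background and multiplier 0.5 a linear truth is recovered
within ±10%.

The null behaviour — no structure invented when presences carry no
signal — is exercised with a presence set whose empirical distribution
equals the background's (the background points themselves), the exact
null for which the penalized gradient vanishes at β = 0; a finite random
subsample would add O(sd/√m) sampling noise that the default penalty is
not designed to absorb completely.

Output: raw(z) = exp(η(z) − α) with α fixed at training so raw sums to 1
over the training background; cloglog p = 1 − exp(−e^H·raw) truncated to
[0, 1], with H the entropy of the fitted background distribution.
Projection clamps each variable to its training range ("fading by
clamping" is implemented as hard clamping; the additional fade blending
toward the training mean found in some MaxEnt builds is not replicated).
The minimum-training-presence threshold is the smallest cloglog value at
any training presence (zero training omission by construction); it
yields a derived binary map and is never used in suitability sums.
Models serialize to JSON (ranges, features, coefficients, α, H, trace
essentials) so projections are reproducible bit for bit. Exact numerical
replication of the MAXENT v3.4.1 binary is a non-goal.

## Model selection and evaluation

- AICc: lnL is the sum over presences of the log of raw normalized to
  sum to 1 over the landscape cells; k counts nonzero coefficients;
  AICc = 2k − 2lnL + 2k(k+1)/(m−k−1), undefined (excluded from ranking)
  when m ≤ k + 1. Candidates are the six feature-class combinations
  (l, lq, lqh, lqhp, lqpt, lqhpt) × multipliers 0.5–4.0; the ΔAICc = 0
  candidate is selected.
- checkerboard2: two nested checkerboards (aggregation factors (2, 2) by
  default — fine boards of 2×2 raster cells, coarse of 4×4) assign
  points to 4 spatially structured bins from the parities of their fine
  and coarse board cells; presences and background are partitioned by
  the same rule. The partition is deterministic. During tuning the
  checkerboard bins drive a 4-fold spatial omission estimate reported
  per candidate; selection itself is by ΔAICc, and fivefold random-fold
  cross-validation evaluates the selected configuration — the
  tuning/evaluation split adopted here.
- partial ROC: sensitivity (on the test points) against the proportion
  of the landscape predicted suitable, swept over 500 thresholds;
  only the low-omission region (sensitivity ≥ 1 − E, E = 0.05)
  contributes; the statistic is the partial AUC divided by the random
  expectation on the same region, averaged over 1000 bootstrap
  resamples of 50% of the test points; the p-value is the proportion of
  bootstrap ratios ≤ 1. E, the iteration count and the resample
  fraction follow the established partial-ROC convention. Random
  predictions calibrate to a ratio of 1 within 0.05 (tested).
- jackknife: regularized training gain is the unpenalized part of the
  fitted objective (the uniform null has gain 0); each variable is refit
  alone and left out in turn.
- percent contribution: each accepted optimizer step's objective
  improvement is credited to features in proportion to
  |Δβ_j|·|gradient_j| and passed to the features' underlying variables,
  product features splitting equally; totals are normalized to 100%.
  With full-vector proximal steps this credit rule is an approximation
  to per-coordinate accounting; it is not claimed to replicate any
  particular MaxEnt build's contribution table, and the tested
  guarantees are non-negativity, normalization, and that a variable
  constructed to drive presence receives the largest share.

## Aggregation and the validation rule

Total suitable habitat S is the sum of cloglog values over valid cells
whose centers fall in a region (NE Florida: −82…−80 × 28…31; Florida:
−87…−79 × 24…31; plus the full extent). Group means are arithmetic
means of member species' S. Percent change versus the present is
computed from unrounded group-average sums (not as the mean of
species-level changes); ratios are mangrove:salt-marsh group means.
Reported tables round sums and percent changes to 1 decimal and ratios
to 3; all comparisons use unrounded values. The validation verdict is
the conjunction of three group-level ordinal criteria: mangrove mean S
lower in the salt-marsh dominance window than the mangrove dominance
window; salt-marsh mean S lower in the mangrove dominance window than
the salt-marsh dominance window; and the mangrove:salt-marsh ratio
higher under mangrove dominance. Species-level orderings are reported
for information but cannot fail the verdict — individual species are
known to deviate from their group's trend.

## Synthetic data

The generator emulates the structure of gridded monthly climate normals
and specimen-based occurrences:

- temperature: base 27 °C at the equator minus 0.45 °C per degree
  latitude, a 6 °C seasonal cosine peaking in July, i.i.d. cell noise
  (sd 0.8 °C), and per-period offsets; tmin/tmax sit half a diurnal
  range (8 °C + 0.05 °C per degree latitude + noise, floored) below and
  above the mean;
- precipitation: 90 mm/month plus 1.2 mm/month per degree longitude
  eastward, a 35 mm seasonal cosine, noise (sd 12 mm), per-period
  offsets, floored at 0;
- elevation: a low (< 10 m) coastal band of columns rising steeply
  inland, with the maskable fraction controllable (default 0.3);
- occurrences: cells drawn with probability ∝ exp(η_truth) for a truth
  model linear in BIO variables, jittered uniformly within the cell,
  with optional injectable contamination (duplicates, (0, 0) records).

Every generator seeds a per-(year, month) child stream from the scenario
seed, so any subset of years reproduces a full run bitwise.

The two-group study scenario uses two cold-limited "mangrove-like"
truths (positive coefficients on BIO6) and two precipitation-tracking
"salt-marsh-like" truths (positive coefficients on BIO12), with the
salt-marsh dominance window cold and wet (−2.5 °C, +30 mm/month), the
mangrove dominance window warm and dry (+1.2 °C, −35 mm/month), the
present neutral, and futures progressively warmer and drier. Offsets
pass through the bioclim computation analytically (a −2.5 °C offset
lowers BIO6 by exactly 2.5 at zero noise — tested), so the imposed
oscillation is recoverable by construction and the inverted scenario is
a genuine negative control. Desk-scale defaults keep every
full-pipeline run in seconds on one CPU: a 100 × 120-cell grid (0.3°
cells — large enough to sample 5,000 background points without
replacement after masking), 6-year windows, 2 species per group, 600
occurrences per species, linear+quadratic features. What passing these
tests shows is that the pipeline discriminates a climate signal it was
built to expose; what it cannot show is performance under real-data
pathologies the generator omits — spatial sampling bias in specimen
records, coastline geometry, spatially autocorrelated noise,
disequilibrium between climate and occupancy, and dispersal or biotic
constraints.

## Pipeline

The `coastsdm` CLI wraps the same library calls behind a YAML config
(defaults reproduce the standard settings: r = 0.7, 10 m elevation
cutoff, n_min = 50, 10,000 background points, the six-window layout).
Stages write versioned artifacts and a manifest (config hash, seed,
stage timings, per-output SHA-256); identical config and seed reproduce
identical checksums (tested). `windows` and `groups` given in a config
replace the defaults wholesale; other sections merge. The `validate`
stage exits nonzero when the verdict is negative, so shell pipelines
fail loudly on an unvalidated model set.

## Known limitations

- Sea-level-rise masking of future coastlines, dispersal constraints
  and biotic interactions are out of scope by design.
- No CRS reprojection; all inputs must share one lat/lon grid.
- The percent-contribution credit rule and hard clamping are documented
  approximations (above).
- Salt-marsh reference sums are not carried in the acceptance tables;
  salt-marsh behaviour is checked ordinally (criteria B and C), not
  numerically.
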