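# Methods

This note records the models, conventions and numerical choices behind
`rangeshift`, and what the synthetic tests do and do not demonstrate.

## Raster model and geometry

Grids are geographic (lon/lat, degrees), square-celled, row 0 northmost.
Nodata is a boolean mask internally, whatever sentinel the file used.
Point-to-cell lookup uses half-open intervals `[edge, edge + res)`.
Cell areas use the spherical-zone formula
`R²·Δλ·(sin φ_top − sin φ_bottom)` with the WGS-84 authalic radius
R = 6,371.0088 km; summed over a global 1° grid this reproduces the
sphere's area to <0.01%. No projected-CRS support and no resampling: all
inputs must share geometry exactly, and every module raises on mismatch.
GeoTIFF georeferencing is carried in the standard ModelPixelScale /
ModelTiepoint / GDAL_NODATA tags; ESRI ASCII grids are supported as the
plain-text interchange format.

## Suitability model

The core is a penalized Gibbs (log-linear) density over background
cells — the presence-background maximum-entropy model. Predictors are
min-max scaled to the training range (clamped on projection, since future
scenarios may exceed it) and expanded into feature classes:

- L: z; Q: z²; P: all pairwise zᵢzⱼ;
- H: forward hinges max(0, (z−k)/(1−k)) and reverse hinges
  max(0, (k−z)/k) at 30 evenly spaced knots each (defaults);
- T: step indicators z > k at 30 evenly spaced interior knots.

Evenly spaced knots are a deliberate simplification of data-driven knot
placement; with 30 knots per direction the hinge basis is dense enough
that placement barely matters at these sample sizes.

The objective is convex: minimize
`−mean_p η + ln mean_b exp(η) + Σ_j λ_j |β_j|`, solved by FISTA with
backtracking and adaptive restart, converged when the objective change
drops below 1e-7 (error with the last objective after 20,000 iterations;
in practice a few hundred suffice). Presence cells are included in the
background and duplicates within a cell are collapsed, so the state
space is the set of distinct training cells.

Penalties are `λ_j = rm · base(class, n_presence) · s_j` with `s_j` the
feature's standard deviation over the background (floored at 1e-3) and a
fixed interpolation table for `base`: L/Q 1.0→0.2→0.05 at n=10/30/100,
P 2.6→1.6→1.0 at 10/17/30, T 2.0→1.0 at 10/100, H 0.5 throughout. Note
the deliberate absence of a 1/√n factor: presence-mean sampling noise
shrinks like 1/√n while λ stays fixed, so with enough presences truly
uninformative features are driven exactly to zero and a no-signal data
set yields an (almost) constant map. This is the package's regularization
convention; it departs from implementations that scale λ by 1/√n and is
the reason the null-data and uninformative-contribution properties hold.

Outputs: raw = exp(η)/Z with Z the background mean of exp(η) (so raw
averages 1 over training background, checked to 1e-6), and
cloglog = 1 − exp(−e^(H−ln N)·raw), H the Shannon entropy of the fitted
distribution over the N background cells. cloglog is a strictly monotone
transform of raw, so ranking metrics (AUC, Spearman) are identical
between the two.

Variable importance: *percent contribution* is permutation importance —
the drop in training gain when one predictor's values are permuted across
the training cells (mean of 10 permutations, floored at 0, normalized to
sum 100). *Jackknife* refits with each variable excluded and alone and
reports unpenalized training gains.

## Occurrence preparation

Thinning enforces pairwise great-circle (haversine) distance ≥ d
(default 1 km): repeatedly delete a random member of the most-conflicted
set until conflict-free, then re-add any deletable point that no longer
conflicts — the result is always a maximal independent set of the
conflict graph. The best of `n_repeats` randomized passes (most points
retained) is returned; everything is seeded.

The sampling-density raster counts target-group records per cell and
smooths with a Gaussian kernel (default σ = 5 cells; σ = 0 gives raw
counts; mass is conserved away from edges). Background cells are drawn
without replacement ∝ density, one point per cell at the cell center,
since predictors are constant within a cell.

## Variable screening and tuning

Screening is two-step: (1) mean permutation contribution over bootstrap
resamples of the presences (default 5 replicates) must exceed 3%; (2)
greedy Spearman pruning at |ρ| > 0.7 over shared valid raster cells, in
priority order of descending mean contribution, so the stronger member
of a correlated pair survives. The result is independent of candidate
input order given the priority list.

The tuning grid crosses six feature sets (L, LQ, H, LQH, LQHP, LQHPT)
with multipliers 0.5–8.0 in 0.5 steps under 10-fold random CV and
4-quadrant spatial-block CV (split at the median longitude/latitude).
Metrics per candidate: fold-mean test AUC (presences vs background,
Mann–Whitney form with ties at ½), AUC_DIFF = train − test AUC, the 10%
training-omission rate (type-7 linear-interpolated quantile threshold —
omission rates are sensitive to the quantile rule, hence it is pinned),
and AICc = 2k − 2 ln L + 2k(k+1)/(n−k−1) with k the count of non-zero
coefficients and ln L the raw Gibbs log-likelihood over all landscape
cells (error when n ≤ k+1). Selection is either `aicc_min` or
`sequential` (lowest omission, then highest test AUC); ties prefer the
lower multiplier, then the simpler feature set. Metrics are averaged
over folds rather than pooled.

## Dispersal limits

Cost surfaces: ordered half-open value-range → cost rules per layer
(first match wins), costs in [1, 1,000,000]. Barriers are coded by
magnitude (1,000,000), not nodata, so they remain traversable at
astronomical cost. The suitability-derived surface assigns the barrier
cost below MTSS and a geometric (log-linear) decay from 1,000 at MTSS to
1 at suitability 1 above it (integer-rounded); the 1,000 top value is a
config knob, chosen so that crossing marginal habitat is ~three orders of
magnitude costlier than moving through optimal habitat. Surfaces merge by
cellwise maximum (most conservative).

Cost distance is multi-source Dijkstra over the 8-connected grid graph,
step cost = mean of the two cell costs, ×√2 on diagonals (the standard
GIS cost-distance convention); sources are the occurrence cells at
accumulated cost 0; unreachable and nodata cells carry +∞. Verified
exactly against an independent graph-library shortest path on random
grids.

Jenks natural breaks uses the exact weighted Fisher dynamic program on
distinct values (verified against exhaustive partition enumeration at
small n). Above 100,000 finite cells or 8,192 distinct values, values are
first histogrammed into 1,024 bins and the DP runs on bin centers — a
documented approximation whose objective stays within a few percent of
exact on bimodal test data; returned class bounds are always actual data
values. The dispersal limit keeps the lowest of 7 classes; source cells
are always inside.

## Range change

Binary maps: suitability ≥ threshold (closed lower bound) AND dispersal
mask, nodata false. Suitable uses each scenario's MTSS; optimal uses 0.8.
Because one fitted model is projected to all scenarios, the training
scores — and hence MTSS — are shared across scenarios; the summary API
accepts per-scenario thresholds for workflows that refit per scenario.
Percent decrease is reported to one decimal. The elevational-shift test
is a two-sided Mann–Whitney U between the elevation multisets of the two
binary maps: exact enumeration for tie-free samples of ≤50, normal
approximation with tie correction otherwise; the reported direction is
the sign of the future-minus-current median. p-values are reported raw,
with no multiple-testing correction across scenarios (the summary table
mirrors the conventional reporting format).

## Synthetic landscapes

The generator emulates a temperate mountain peninsula: Gaussian-smoothed
white-noise terrain (σ = 6 cells) scaled to ~0–2,000 m with the lowest
12% masked as sea; slope from the finite-difference gradient, scaled into
0–35°; temperature = 13 °C − 6.5 °C/km × elevation + 0.8 °C/degree-lat
gradient + N(0, 0.3) noise; seasonality, isothermality and two
precipitation fields as smoothed fields with terrain coupling; two
forest covers as logistic transforms (mixed forest increases with
elevation; needleleaf is deliberately independent of everything).

True suitability is cloglog(η) of standardized layers with fixed
coefficients describing a montane specialist (steep slopes, cold, wet,
mixed forest); needleleaf cover and isothermality have coefficient 0 and
are the uninformative controls. The sampling-bias field is a smooth
accessibility surface favouring low ground; presences are drawn without
replacement ∝ suitability × bias^strength and jittered within the cell.
The target group (several species with their own smooth preference
fields) is drawn with the *same* bias exponent as the focal species —
that records of related taxa share the focal survey's spatial bias is
precisely the assumption that makes target-group background correction
valid, and the generator enforces it. Future scenarios shift temperature
additively and scale precipitation multiplicatively, leaving terrain and
forest bit-identical; an optional smooth anomaly field (off by default)
can make warming spatially heterogeneous.

What the synthetic tests show: that the pipeline recovers a known
suitability ranking (Spearman ρ ≈ 0.92–0.97 at 500 presences across
seeds) through strong, shared, *estimable* sampling bias, and that its
statistics behave as designed. What they do not show: robustness to bias
that the target group does not share (regional taxonomic gaps), to
niche shapes outside the log-linear family, to label noise or
misidentification, or to real spatial autocorrelation structures in
climate data — real-data performance claims need real data.

## Problem sizes

Default study conditions for the recovery analyses: 120×160 cells,
500 presences (bias exponent 2), 8×250 target-group records, 4,000
background cells, full LQHPT basis at rm = 1.5. The bundled pipeline
fixture uses 48×64 cells so an end-to-end run completes in seconds; the
tuning grid in the demo config is reduced to a 3×3 subset of the full
6×16 grid, which the `tune` API exposes in full.
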