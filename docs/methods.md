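# Methods

This note documents the models, numerical conventions and design choices
behind `equirep`, and what the synthetic landscapes do and do not establish
about real protected-area data.

## Sampling model

All analysis happens on a regular lon/lat lattice (default 0.1° cells,
WGS84). Cell areas are geodesic: geometries are projected onto a cylindrical
equal-area surface of the authalic sphere (R = 6371.0072 km), where planar
area equals spherical surface area. Cells, protected polygons, and their
intersections are all measured through this one transform, so gridding the
dissolved network conserves its total area to float precision (the 0.5%
tolerance in the tests absorbs only slivers falling outside the grid or the
territory polygons). Departures from ellipsoidal areas are below 0.3% and
cancel in every ratio the pipeline reports.

Protected-area records are polygons, or points carrying a reported extent in
km². Points become circles of radius √(extent/π), drawn in degrees with the
east–west axis stretched by 1/cos(latitude); the circle's geodesic area
matches the reported extent to well under 1% for extents up to 10⁴ km². A
buffered circle that intersects an existing protected *polygon* is discarded;
the rule is deliberately not applied between two buffered circles — that is
the literal reading of the exclusion rule this pipeline implements, and the
filter report makes the decision auditable.

Networks are cumulative: the snapshot at cutoff year *y* is the union of all
units with establishment year ≤ *y*. Records with a missing year are included
in every snapshot by default (configurable to exclude), since a cumulative
register without a stated missing-year rule is most faithfully read as "the
unit exists throughout". Cells shared by several territories are split by
territory polygons, and each territory's statistics see only its own share.

Raster layers are aggregated into cells with per-variable statistics: mean
for the climatic/topographic/edaphic layers, border distance and cropland
suitability; sum for population; minimum for distance to roads (the nearest
road determines a cell's accessibility); and the ratio of total photos to
total population for tourism attractiveness.

## Binning and PEx

Histograms have a fixed 10 classes per gradient. Interior edges divide the
range between the 2.5% and 97.5% *area-weighted* quantiles into equal-width
intervals; the outer edges extend to the data minimum and maximum, so tail
observations are grouped into the first and last class and no land is
dropped — histogram totals are invariant to the trimming parameters.
Intervals are half-open [lo, hi) with the last closed. The area weighting
reflects that the sampling unit is a cell of varying geodesic area;
cell-count weighting is available but not the default.

The weighted quantile interpolates linearly between order statistics at
positions p_k = (S_k − w_k)/(S_n − w_n) (S_k the running weight sum), which
reduces exactly to numpy's default linear rule for equal weights. The rule is
fixed so results are reproducible bit-for-bit; note it is not exactly
invariant under subdividing a cell (edge shifts are bounded by one cell's
weight), whereas PEx itself is — subdividing a cell never changes a
histogram.

A variable that is constant over a territory has no gradient to bin and
raises a "degenerate gradient" error rather than returning a meaningless
equality. Empty interior bins carry PEx = 0 and are flagged: an unrepresented
condition is maximal inequality, which is exactly what the representation
concept intends, but the flag keeps it visible. The Sturges alternative uses
⌈1 + log₂ N⌉ classes with the same trimming; the test-suite ensemble checks
that territory rankings by G′ are strongly concordant between the two rules.

## Equality

G is the rank-based Gini of the PEx vector after sorting ascending; without
the sort the printed formula is not a Gini at all, and with it the formula is
algebraically identical to the pairwise mean-absolute-difference form (the
test suite verifies agreement to 1e-12 on random vectors, with the
brute-force form as an independent oracle). Two boundary conventions matter:

- **All-zero PEx raises** (`UndefinedEqualityError`) instead of returning a
  number. "No protection at all" and "maximally unequal protection" are
  different findings and must not be conflated in downstream averages.
- **A single nonzero class gives G′ = 1/n, not 0.** The rank formula's
  minimum for finite n is (n−1)/n, so with ten classes the floor of G′ is
  exactly 0.1; the informal description of this case as "equality 0" is true
  only in the n → ∞ limit. The implementation follows the formula.

Collinearity pruning is a single left-to-right pass over consecutive pairs of
the active variable list in the fixed analysis order (temperature,
precipitation, elevation, slope, soil fertility): when |τ| (tie-corrected
Kendall τ-b) between an active variable and the next exceeds 0.55, the
*earlier* variable is eliminated and the pass continues from the survivor.
This is the literal reading of "eliminating variable *i* against variable
*i+1*"; an iterative re-testing variant is available behind a flag, and the
`CollinearityReport` records every comparison so alternative choices are
auditable. If fewer than two variables survive, the mean G′ rests on a single
gradient and a warning is recorded.

A territory's score is the arithmetic mean of the retained variables' G′;
variables with undefined equality are skipped with a warning. On the
biogeographical basis, G′ is computed across the PEx values of the
territory's ecoregions; a single-ecoregion territory has no diversity to
balance and its equality is reported as undefined, never as zero.

Trajectories evaluate extent and mean G′ at decadal cutoffs (≤1960, 1970, …,
2010, 2016). Decade-to-decade efficiency is the raw difference quotient
ΔG′/Δextent, undefined when the network did not grow — no smoothing.

## Priority

Pr_k is the mean over retained gradients of (100 − PEx of the cell's bin),
using current-period histograms. National maps bin and prune per territory;
the continental map recomputes histograms and pruning over the full extent as
one unit, which is why a condition common in one country but rare overall can
change class between the two maps. Quantile classes (quartiles or deciles)
have equal cell counts (±1) with ties broken by cell id; an all-tied map is
still balanced and flagged degenerate.

## Drivers

The response of the random forest is each cell's protected *fraction* (a
regression target — %MSE importance is only defined for regression forests);
a binary-presence mode would be a trivial variant but the continuous fraction
uses the available information. The forest is bagged regression trees
(ntree = 500, terminal node size 1 by default) with mtry chosen to minimize
the aggregated out-of-bag MSE (ties take the smaller mtry). Importance
follows the classic %IncMSE convention: per tree, the OOB MSE increase when
one variable is permuted, averaged over trees and scaled by its standard
error. Reported importances are normalized to percentage shares of the total
(negative raw values clipped to zero), which makes them comparable across
territories; the unnormalized values are also kept, since "no better than
noise" is only visible on the raw scale.

Uncertainty comes from refitting on B = 1000 bootstrap resamples of the cells
(mean ± sd over replicates). One subtlety: when the training data is itself a
bootstrap resample, a duplicated cell can be in-bag and nominally
"out-of-bag" at once, and a fully grown tree has memorized it — which inflates
every permutation importance. Out-of-bag membership is therefore defined by
cell identity: a row counts as OOB for a tree only if no copy of its cell is
in that tree's bag. Without this correction a pure-noise response shows
strongly positive importances; with it, the null is centred on zero.

Two predictors that are copies of each other split their importance rather
than doubling it — both still exceed noise level, but neither alone reflects
the full signal; the tests assert this qualitatively.

## Synthetic landscapes

The generator emulates three ingredients, all pure functions of (spec, seed):

- **Fields**: unit-variance white noise smoothed with a Gaussian kernel
  (autocorrelation length in cells), scaled by a noise amplitude, plus a
  linear large-scale trend; heavy-tailed fields (population, tourism) are
  exponentiated. Defaults are order-of-magnitude realistic for a subtropical
  study region (e.g., temperature ~25 °C with an 18 °C poleward decline,
  precipitation 400–2000 mm) so that percentile binning yields non-degenerate
  classes; they are not climate physics.
- **Territories and ecoregions**: Voronoi partitions of random seed points —
  contiguous regions with irregular borders; the partition property (every
  cell in exactly one region) is guaranteed, geography is not.
- **Networks**: three placement scenarios with machine-readable ground truth.
  *uniform* protects a centred sub-rectangle of every cell covering the
  requested fraction of its area, split into per-unit slivers so the network
  is spatially uniform at every decadal cutoff — this makes the expected PEx
  exactly equal across bins, the property the scenario exists to plant
  (whole-cell random placement would add ~1-point sampling noise per bin).
  *single_bin* protects whole cells drawn from one class of one gradient,
  erroring with the shortfall if the class cannot supply the requested area.
  *biased* draws whole cells without replacement with log-odds proportional
  to minus the driver's rank normal-score (Gumbel-max sampling) — rank-based
  so the bias strength means the same thing for heavy-tailed and symmetric
  drivers. Establishment years are drawn per unit from a decade distribution
  (1930–2010 by default, capped at 2016). A configurable fraction of units
  (default 5%, biased scenario only) is emitted as point+extent records to
  exercise the buffering path; the uniform and single-bin scenarios force
  polygons, since a buffered circle could not respect their exact-placement
  guarantees.

Passing the planted-scenario tests shows the statistics recover known
structure under smooth fields, exact category labels, and exhaustively known
establishment years. Real registers have misreported extents and years,
category ambiguity, coastlines and partial land cells (supported via the
land-fraction column but defaulting to 1), and gradients whose collinearity
structure is far stronger than the defaults — none of which the synthetic
tests exercise.

## Problem sizes and numerical choices

The test and acceptance runs use landscapes of 400–10 000 cells, forests of
60–100 trees with B = 50–100 bootstrap replicates over 20 landscape seeds —
sizes chosen so the full suite completes in minutes on one core while leaving
every statistical margin wide (the planted-driver recovery, for instance,
passes at 100% against a 95% requirement). API defaults keep the full-size
settings (10 bins, τ threshold 0.55, ntree = 500, B = 1000). All randomness
flows from explicit integer seeds through `numpy` generators; identical
configuration and seed reproduce every artifact checksum-identically.

## Known limitations

- Areas are spherical (authalic), not ellipsoidal; the error is uniform in
  longitude and below analysis noise, but boundary-length computations (not
  needed here) would be less forgiving.
- The buffered-circle construction degrades near the poles (cos φ → 0); the
  intended study domains are tropical-to-temperate.
- Pruning depends on the fixed variable order, by design; a different order
  can retain a different set. The report exists to make that visible.
- The continental scope pools cells with equal weight regardless of
  territory, so one large territory can dominate continental histograms —
  faithful to the "continent as a single unit" definition.
- `sample_layers` assigns raster pixels to cells by pixel centre; rasters
  whose resolution does not divide the cell size evenly get slightly uneven
  pixel counts per cell.
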