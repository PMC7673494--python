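# Methods

This note records the modelling choices in `sdmconnect`: what each
stage computes, the assumptions behind it, the parameters that matter,
and the decisions taken where the workflow it replays left details
open.

## Spatial model

All grids are projected, equal-area, in meters; row 0 is the
northernmost row, cell centers sit at `(x_min + (j+0.5)·cell, ...)`,
and point-in-cell tests use half-open cell extents.  Areas come from
cell counts, so geographic (degree) inputs are rejected rather than
silently reprojected.  ESRI ASCII grids are written with 6 significant
digits; GeoTIFFs carry the standard ModelPixelScale / ModelTiepoint /
GDAL_NODATA tags.

Derived layers follow their canonical published forms: Euclidean
distance-to-feature surfaces; hillshade from Horn slope/aspect,
`255·max(0, cos z cos s + sin z sin s cos(az − aspect))`, averaged over
12 monthly solar-noon positions at the configured latitude (the
"annual shade" product names a toolbox, not a sun sampling, so the
monthly-noon design is ours); and a fragmentation index counting, in
each 3×3 window, the fraction of rook-adjacent cell pairs with
differing land-cover classes (12 pairs in the interior, fewer at
edges; pairs touching nodata are dropped from both counts).  This
reproduces the documented 0–1 range of the original raster-GIS filter;
its exact internal formula is not published, so agreement is by range
and behavior, not bit-compatibility.

## Synthetic landscape

The generator emulates the statistical structure the analysis assumes
rather than any real geography:

- **Layers.** Gaussian white noise convolved with a Gaussian kernel
  (`range_param = 8` cells, i.e. 8 km autocorrelation length), then
  whitened against its empirical covariance and mixed by the Cholesky
  factor of the target correlation matrix — so inter-layer correlations
  hit their targets essentially exactly, not merely in expectation.
  The default stack has ten layers named after the habitat variables of
  a montane carnivore study (bio* climate layers respond to scenario
  shifts; terrain layers do not), with one engineered collinear pair
  (`r(bio3, bio11) = 0.85`) so the pruning stage has real work.
- **Truth.** Suitability is `sigmoid(β0 + Σ β_j z_j)` over standardized
  layers with `β0 = −2`, `β = {bio19: +3, bio7: −2, bio17: +2}` — a
  relatively rare species strongly driven by three climate variables.
  The magnitudes are chosen so the fitted models operate in the same
  high-discrimination regime the original field validation reported
  (AUCs near 0.96–0.99): presences concentrate in coherent suitable
  patches and are separable from envelope-based pseudo-absences.  A
  weaker truth (|β| ≈ 1) leaves even the true model near AUC 0.73 on
  this sampling design, which would say nothing about the pipeline.
- **Occurrences.** 80 presence cells drawn without replacement with
  probability proportional to truth; points at cell centers, so
  duplicates are impossible by construction (real workflows deduplicate
  by thinning instead).
- **Nodes.** Six disjoint quasi-circular protected areas (radius
  6 ± 40% cells) with a one-cell moat so contracted supernodes never
  touch.
- **Scenarios.** Additive/multiplicative shifts of climate layers only
  (default: a mild and a severe drying-warming combination).  These are
  stand-ins for downscaled circulation-model stacks, not climate
  projections.

What the generator does *not* emulate: observation bias, spatially
clumped survey effort, label noise, non-stationary species-environment
relationships, and real terrain. Passing tests demonstrate the
pipeline's internal correctness and its ability to recover a known
truth under clean conditions — not field performance.

## Occurrence preparation

- **Pruning**: greedy — while any pair of layers has |Pearson r| > 0.75
  over jointly valid cells, drop the member with the larger mean
  absolute correlation to the remaining layers (ties alphabetical).
  Deterministic, idempotent, and standard practice; it does not search
  for the globally largest retained subset, though it attains it on
  small instances (verified against exhaustive search in the suite).
- **Thinning**: distance-only greedy rarefaction — repeatedly delete
  from the closest violating pair the member with more neighbors
  within the 5 km radius (ties by seeded RNG), after canonically
  sorting the input so record order is irrelevant.  The workflow this
  replays additionally ranked points by terrain heterogeneity; distance
  is the binding constraint it reported, so heterogeneity
  stratification is deliberately out of scope.
- **Pseudo-absences**: the 5 km exclusion is applied both against
  presences and mutually among pseudo-absences (the stricter of the two
  readings of the rule; it prevents clumped absences).  Candidates are
  cells the presence-only majority ensemble calls unsuitable, visited
  in seeded random order until the 2× quota is met.

## The model zoo

All learners consume z-standardized predictors (constants frozen at fit
time) so the defaults are scale-free: one-class SVM `nu = 0.1`,
`gamma = 1/p`; SVM `C = 1`, `gamma = 1/p`; ANN 8 hidden logistic units,
500 epochs, Adam, seeded; MaxEnt L1 penalty `β = 0.05` per feature,
linear + quadratic features only (hinge features are a larger-sample
tool).  SVM-family fits are optimized by scikit-learn, but decision
functions are evaluated from the stored support vectors / weights, so
models serialize to JSON and round-trip exactly.  Training rows are
canonically sorted before any iterative fit, making every model
invariant to record order.

Numerical choices worth noting:

- **GLM**: IRLS with convergence at max |Δβ| < 1e−8 or 100 iterations;
  rank-deficient designs get the minimum-norm solution; suspected
  perfect separation (non-convergence or exploding coefficients)
  triggers a ridge refit (λ = 1e−6) and is flagged in the parameters.
- **MaxEnt**: the presence log-likelihood of the Gibbs density
  `exp(η·f)/Z` over background cells is maximized by proximal gradient
  (ISTA) with backtracking line search; the continuous output is
  `sigmoid(η·f + c)` with `c` bisected so the mean training-presence
  score is 0.5.  The output transform of the original tool is
  undocumented; this convention is pinned and tested instead.
- **Presence-only thresholds**: each PO model is binarized at its
  minimum training-presence score (zero-omission threshold), and the
  three binaries combine by majority vote — both config-pinned, since
  the replayed workflow says only that the models were "integrated".

## Evaluation and ensemble

AUC is the Mann-Whitney form with midranks; its standard error is
Hanley-McNeil with `Q1 = A/(2−A)`, `Q2 = 2A²/(1+A)` evaluated at the
observed A (recorded convention), the null test is
`z = (A − 0.5)/SE`, and the 95% CI is the normal approximation clipped
to [0, 1].  TSS is swept over all unique scores plus {0, 1} with the
strict rule "positive when score > θ"; ties in the argmax resolve to
the smallest threshold.  The identities TSS = Se + Sp − 1 and
misclassification = 1 − correct are asserted on every report the
package builds.

Ensemble weights are `AUC_i / Σ AUC_j` — the plainest reading of
"accuracy rate as weight" — with `AUC − 0.5` skill weighting available
in config; members at AUC ≤ 0.5 are rejected with a warning.  The
binarization threshold defaults to the max-TSS threshold computed on
all occurrence points (the stacked-binary convention); a held-out-only
mode is switchable, since which convention the replayed tables used is
ambiguous.  With fewer than two fitted models no ensemble row is
produced and the single model's map flows downstream unchanged.

## Connectivity

`R = 1/max(s, 0.01)` is the literal inversion of suitability, bounded
in [1, 100]; a linear alternative `R = 1 + c(1 − s)` is in config.
Edge conductance is the series average `2/(R_i + R_j)`, diagonals
divided by √2 for the longer span (8-neighborhood default, 4
switchable).  Focal regions are contracted to supernodes (zero internal
resistance), which makes "inject 1 A at the source" well-defined for
multi-cell and non-contiguous (administratively merged) nodes.  The
grounded sparse Laplacian system is solved by LU factorization; cell
current is half the sum of incident branch currents, with terminal
cells assigned the full injected ampere so map maxima are comparable
across pairs.  Disconnected pairs report infinite effective resistance
and a zero current map rather than failing.  Pinch points are cells at
or above the 0.999 quantile of nonzero cumulative current; the
comparison carries a 1e−9 relative tolerance so threshold ties are
included under last-bit solver jitter.

## Importance

The forest draws its own bootstrap per tree (scikit-learn CART
underneath) so out-of-bag index sets are first-class: permutation
importance is the per-tree OOB accuracy drop after shuffling one
variable's OOB values, averaged over trees, with per-class variants on
each class's OOB rows; Gini importance accumulates
`(parent − weighted children) · node fraction` over each variable's
split nodes.  Values are reported on the raw accuracy-decrease scale;
tool-specific rescalings of published tables are not chased.  Defaults:
500 trees, `mtry = floor(sqrt(p))`.

## Reproducibility and problem sizes

Every stochastic stage derives its seed as `crc32(stage ":" seed)` from
the single global seed, so stages can be re-run in isolation and two
runs of the same config are bit-identical (the output manifest hashes
every file).  The default replay uses a 150×150 km landscape at 1 km
resolution with 80 presences — large enough for the spatial constraints
(5 km thinning and exclusion radii) to bind and for a ~200-point
model table, while keeping a full replay under ten seconds.  The
held-out test split at these sizes is ~40 points, so single-seed AUCs
carry sampling noise of a few hundredths; conclusions about recovery
are drawn from multi-seed runs (the importance recovery rate is
measured over ten seeds).

## Known limitations

- The fragmentation filter and the MaxEnt output transform match their
  originals in behavior and range, not bit-for-bit.
- The Hanley-McNeil SE at the observed A is one of several published
  conventions; CIs are normal-approximate, not bootstrap.
- Greedy pruning and greedy thinning are deterministic heuristics, not
  global optima.
- Connectivity supports pairwise mode only (no all-to-one modes, no
  short-circuit polygons beyond node labels).
- The synthetic landscape is stationary and bias-free; transfer of any
  quantitative result to field data is out of scope.
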