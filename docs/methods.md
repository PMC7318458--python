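# Methods

`scpsens` studies how sensitive spatial conservation prioritisation is to
the analytical choices made upstream of it. Every stage operates on an
abstract raster grid (0-based, row-major, top-left origin) whose valid
cells form the landscape; there is no coordinate reference system.

## The prioritisation engine

The engine ranks cells by iterative removal: starting from the full
landscape it repeatedly deletes the cell whose loss costs the least
conservation value, so the cells that survive longest are the most
valuable, and top-fraction sets are nested by construction. Inputs are
per-species occupancy fractions `q_ij` (each species' suitability map
normalised to sum 1 over valid cells) and strictly positive species
weights `w_j`.

Two marginal-loss rules are implemented:

* **Core-area (CAZ)** — the loss of cell *i* is
  `max_j w_j f_i q_ij / sum_{k in S} f_k q_kj`, the largest weighted share
  of any single species' *remaining* (penalty-discounted) distribution.
  It protects locations that are irreplaceable for at least one species,
  regardless of local richness.
* **Additive benefit (ABF)** — the loss is
  `sum_j w_j [V(R_j) - V(R_j - f_i q_ij)]` with the concave value function
  `V(R) = R^z`, where `R_j` is species *j*'s remaining fraction of its
  original distribution. Concavity makes losses hurt more for species that
  have already lost much; the rule favours species-rich cells. The
  exponent defaults to `z = 0.25` (a conventional choice; exposed as a
  parameter). At `z = 1` the rule degenerates to a weighted richness sum.

**Connectivity (boundary-quality penalty).** A cell's effective
suitability is multiplied by `f = 1 - s (1 - rho)`, where `rho` is the
fraction of its Moore neighbourhood (radius 1-3 cells, focal cell
excluded, clipped to the grid and valid mask; cells with no valid
neighbour use `rho = 1`) still present in the landscape. The response
slope `s` encodes how strongly local populations depend on their
neighbourhood: 0 (none), 0.25 (low), 0.6 (medium), 1.0 (high). The linear
family was chosen for transparency; the slopes reproduce the expected
qualitative ordering (low is nearly neutral, high aggregates solutions
strongly). One shared curve applies to all species. Penalties affect the
removal decision only; performance curves always report unpenalised
fractions of the original distribution. Under CAZ the denominator uses
the penalised remaining sums; under ABF the remaining fractions `R_j` are
unpenalised while the cell's contribution is discounted by `f_i`.

**Masks and determinism.** A hierarchical mask forces urban/agricultural
cells (level 0) to be removed before any free cell (level 1), and free
cells before protected-area cells (level 2) — masking substitutes for a
monetary cost layer. Within a stratum, ties in marginal loss (within a
relative tolerance of 1e-9) break towards the smallest row-major index,
so runs are exactly reproducible. The `warp` parameter removes several
cells per iteration without re-evaluating losses in between; warp 1 is
exact, warp 10 is the approximation used for the factorial experiment.
The engine maintains remaining sums, neighbour counts and penalty factors
incrementally; the test-suite proves order equivalence against a naive
oracle that recomputes everything from scratch each step.

## Species distribution models

Presence-only records are modelled as an inhomogeneous Poisson point
process with log-linear intensity. Fitting uses down-weighted Poisson
regression: all valid cells enter as quadrature points (weight = cell
area, response 0) and each record as a point with weight 1e-6 and
response 1/1e-6; a weighted Poisson GLM then maximises the point-process
likelihood. Two model variants give the factorial its algorithm factor:

* **A** — linear + quadratic environmental terms with a light ridge
  penalty (1e-3), a Maxent-style log-linear model;
* **B** — the same features under an elastic-net penalty (mixing 0.5),
  with the strength chosen per species from {0.3, 0.1, 0.03} by summed
  validation negative log-likelihood over the spatial folds.

Penalised fits run to a relative penalised-deviance change below 1e-8
(capped at 10^4 iterations); the intercept is never penalised.

**Sampling-bias correction** is model-based: accessibility covariates
(distances to the nearest road, city and protected area, plus the
distance to the nearest feature of any class) are included at fit time
and set to zero distance at prediction time. The corrected map estimates
what an unbiased observer would have recorded. The nearest-feature
distance matters: the generator thins detection by the minimum of the
class distances, and without that covariate the bias model would be
misspecified in a way no amount of data repairs.

**Spatial-block cross-validation.** The grid is tiled into square blocks,
dealt to k = 5 folds by seeded permutation (balanced to within one
block). Each fold's model is fitted on records outside the fold and
predicts the whole landscape; the species' prediction is the cell-wise
mean of the five maps. Species with fewer than 8 unique occupied cells or
fewer than 5 occupied blocks are excluded — five occupied blocks are the
minimum for fivefold block cross-validation. Predictive consistency, the
mean Schoener's D (`1 - 0.5 sum |p - q|` on normalised maps) over the ten
fold-map pairs, doubles as an optional species weight: species whose
predictions are unstable under spatial resampling count less.

## Gap analysis

Three statistics compare a ranking (built ignoring protected areas) with
the existing network: the point-biserial (Pearson) correlation between
rank and the 0/1 protection indicator; the Jaccard overlap between the PA
set and the equal-area top-ranked set; and Kendall's tau-b between rank
bins (equal width on rank value, empty bins dropped, default 1%) and the
fraction of each bin protected. Expansion sites are the unprotected cells
of the top target fraction (default 17%, the Aichi-11 area target) of a
second ranking in which PAs are forced to the highest priority.

## The factorial experiment

Seven factors are crossed completely: surrogate taxon (butterflies,
reptiles, mammals, all), SDM algorithm (A, B), bias correction (off, on),
removal rule (CAZ, ABF), weighting (none, Red-List, consistency, both =
product), connectivity (none plus {low, medium, high} x radius {1,2,3} =
10 options) and PA forcing (off, on) — 2560 runs. The response of a run
is the mean remaining representation over the run's own species at the
top 10/17/25% of the landscape, read off its performance curves. SDM
predictions are prepared once per (algorithm, bias) pair and shared
across rows; urban forcing applies in every run.

Two referents of "representation" must be distinguished. The primary
response measures each run against its *own* prediction maps — the only
option with real data, and the one fed to the importance analysis. On a
synthetic world the true intensities are also available, so
`run_design` additionally reports truth-referenced responses
(`response_true_*`): the share of the *true* distributions captured by
the run's top cells. The distinction matters for the sampling-bias
factor: uncorrected maps are more spatially concentrated (suitability is
inflated along accessible areas), so uncorrected runs often score higher
on themselves while protecting less of the actual distributions. The
benefit of bias correction is therefore a truth-referenced statement,
and the tests assert it on `response_true_17`.

Factor influence is attributed two ways. Permutation importance fits a
500-tree random-forest regression of the response on the seven factors,
cross-fitted on two seeded halves; a factor's importance is the mean
increase in held-out MSE over 10 permutations of its column (cross-fitting
keeps the error estimate out-of-sample without relying on forest
internals). First-order interactions are ranked by their ANOVA mean
squares from a linear model with all main effects and two-way terms; on
the balanced design the decomposition is exact and order-independent.

## Synthetic data

The generator produces worlds with the statistical structure the pipeline
assumes, at configurable size. Environmental fields are Gaussian white
noise smoothed with a Gaussian kernel (default sd 5 cells) and
standardised. Accessibility features are random road lines (Bresenham
segments) and city/PA points; each class yields a Euclidean
distance-transform raster. Species log-intensities are linear-quadratic
in the environmental layers with independent N(0, effect_sd) coefficients
(default sd 0.8, giving realistic niche structure including interior
optima); Red-List weights are uniform draws on {1..5}. Presence records
are drawn with replacement with probability proportional to
`intensity * exp(-bias_strength * min distance)` (default bias 0.3);
per-species sample sizes default to log-uniform between 8 and 200
records, spanning data-poor to data-rich species. Masks grow contiguous
protected (default 14.6% of valid cells, mirroring a national PA network
share) and urban (default 5%) blobs by seeded region growing. Every
generator is a pure function of its arguments including the seed.

What the generator does not emulate: real geography and barriers,
spatially varying recording effort beyond accessibility decay,
detection/misidentification error, taxonomic correlation between species,
temporal structure, and range-wide processes larger than the grid.
Passing tests therefore demonstrate the correctness and directional
behaviour of the machinery, not calibrated predictions for any real
landscape.

## Problem sizes and numerical choices

The default experiment scale used by the test-suite and the acceptance
script is a 40x40 landscape with 24 species (8 per group), warp 10 for
the 2560-run factorial, and warp 1 wherever exactness is checked; these
sizes keep a complete desk-scale replication of the analysis cheap while
leaving every structural number (design rows, fold pairs, thresholds)
identical to the full-scale analysis. Engine-versus-oracle equivalence is
proven exhaustively on small grids (<= 20x20), where the naive oracle is
tractable. Degenerate inputs are defined: all-zero species are rejected
at normalisation; species with no remaining distribution are skipped in
CAZ; cells with no valid neighbour take retention 1; a constant
protected-fraction profile leaves Kendall's tau undefined (NaN, logged).
Rasters are float64 in memory and float32 on disk (ESRI ASCII or TIFF,
nodata -9999), with canonical ASCII formatting so rewrites are
byte-identical.

## Known limitations

Warp > 1 is an approximation whose error grows with warp and with strong
connectivity. The linear BQP curves are one member of the plausible
response-curve family; only their ordering, not their shape, is
calibrated. Variant A/B are two penalisation regimes of the same
point-process family, not reimplementations of any external software.
Representation responses across factorial rows share prepared SDM
predictions, so SDM-fit uncertainty enters only through the
algorithm/bias factors, not as replicate noise.
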