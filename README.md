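# scpsens

**Sensitivity analysis of spatial conservation prioritisation.**

Deciding where to place or expand protected areas from models of species
distributions involves a long chain of analytical choices: which taxon
stands in for biodiversity, which model fits the presence-only records,
whether to correct for sampling bias, which cell-removal rule ranks the
landscape, how to weight species, how much connectivity matters, and
whether existing reserves are locked into the solution. `scpsens` makes
that whole chain executable and crosses every choice in a full factorial
so the influence of each can be measured. It is aimed at conservation
planners and spatial ecologists who want to know *which* of their
decisions actually move the map.

The package contains:

* a **greedy reserve-selection engine**: iterative smallest-marginal-loss
  cell removal under the core-area rule
  (`delta_i = max_j w_j q_ij / sum_k q_kj`, guarding irreplaceable sites)
  or the additive-benefit rule
  (`delta_i = sum_j w_j [R_j^z - (R_j - q_ij)^z]`, favouring richness),
  with boundary-quality-penalty connectivity
  (`f = 1 - s(1 - rho)` over Moore neighbourhoods of radius 1-3) and
  hierarchical masks (urban out first, protected areas out last),
  producing nested rank rasters and per-species performance curves;
* **presence-only point-process SDMs** via down-weighted Poisson
  regression (ridge or elastic-net penalised), fivefold spatial-block
  cross-validation, Schoener's-D predictive-consistency weights, and
  model-based sampling-bias correction (accessibility covariates fitted,
  then predicted at zero distance);
* **gap analysis**: point-biserial rank-protection correlation, Jaccard
  overlap of equal-area top sets, Kendall's tau over 1% rank bins, and
  expansion-site selection to an area target (default 17%);
* a **2560-run factorial sensitivity experiment** (4 surrogates x 2
  algorithms x 2 bias options x 2 rules x 4 weightings x 10 connectivity
  options x 2 PA options) with random-forest permutation importance and
  two-way-interaction ANOVA;
* a **seeded synthetic-data generator** (smooth environmental fields,
  linear-quadratic species niches, accessibility-biased sampling,
  contiguous PA/urban masks) so the entire pipeline runs without any
  external data.

## Worked example

```python
from scpsens.grids import GridSpec
from scpsens import synthetic as syn
from scpsens.prioritiser import normalize_features, prioritise, \
    performance_curves, representation_at_top
from scpsens.evaluation import gap_report

grid = GridSpec(40, 40)
env = syn.make_covariates(grid, n_env=3, smoothness=5, seed=1)
access = syn.make_accessibility(grid, n_roads=3, n_cities=5, n_pas=4, seed=2)
pool = syn.make_species_pool(env.merged(access),
                             {"butterfly": 8, "reptile": 8, "mammal": 8},
                             effect_sd=0.8, seed=3)
mask = syn.make_masks(grid, pa_fraction=0.146, urban_fraction=0.05, seed=4)

stack = normalize_features(
    {sp.species_id: sp.true_intensity for sp in pool.species}, grid)
ranking = prioritise(stack, rule="caz", mask=mask)
curves = performance_curves(ranking, stack)
print(f"top-17% representation: {representation_at_top(curves, 0.17):.3f}")

report = gap_report(prioritise(stack, rule="caz").rank, mask.pa_mask,
                    bin_width=0.05)
print(f"jaccard={report.jaccard:.3f}  "
      f"r_pb={report.point_biserial_r:.3f}  tau={report.kendall_tau:.3f}")
```

prints

```
top-17% representation: 0.567
jaccard=0.156  r_pb=0.122  tau=0.484
```

With protected areas forced to the top of the ranking, 56.7% of the
average species' distribution sits in the best 17% of the landscape —
far more than the 17% a uniform landscape would give, because the engine
concentrates on jointly valuable cells. The gap statistics compare an
unconstrained ranking against the (randomly grown) synthetic reserve
network: it overlaps the equal-area top set by only 15.6%, is nearly
uncorrelated with priority rank cell by cell, and protection rises only
weakly toward the high-priority end — the typical signature of a reserve
network that was not placed with these species in mind.

The same pipeline scales up through `scpsens.workflow`; the umbrella CLI
(`scpsens simulate | sdm | prioritise | gap | sensitivity`) exposes each
stage on files (ESRI ASCII or TIFF rasters, CSV tables, YAML configs).

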