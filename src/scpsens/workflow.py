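"""End-to-end orchestration: synthetic world -> SDMs -> factorial -> reports.

Thin glue over the library modules so the CLI and scripted experiments can
run the whole pipeline from one validated configuration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .evaluation import gap_report
from .grids import GridSpec
from .io import RunConfig
from .prioritiser import (
    ConnectivityConfig,
    normalize_features,
    performance_curves,
    prioritise,
    representation_at_top,
)
from .sdm import FoldAssignment, assign_blocks, filter_species
from .sensitivity import (
    PAPER_FACTORS,
    ImportanceReport,
    PreparedInputs,
    build_design,
    interaction_mean_squares,
    permutation_importance,
    prepare_inputs,
    run_design,
)
from .synthetic import (
    CovariateStack,
    MaskLayer,
    SpeciesPool,
    make_accessibility,
    make_covariates,
    make_masks,
    make_species_pool,
    sample_presences,
)

logger = logging.getLogger(__name__)

__all__ = [
    "World",
    "ExperimentResult",
    "build_world",
    "design_for_scale",
    "run_sensitivity_experiment",
    "run_gap_analysis",
]


@dataclass
class World:
    """One synthetic study system shared by all pipeline stages."""

    grid: GridSpec
    covariates: CovariateStack  # env + access merged
    access: CovariateStack
    pool: SpeciesPool
    records: pd.DataFrame
    mask: MaskLayer
    folds: FoldAssignment
    kept_species: list[str]


def build_world(cfg: RunConfig) -> World:
    """Generate the synthetic landscape and data described by the config."""
    g, s = cfg.grid, cfg.simulate
    grid = GridSpec(g.nrows, g.ncols, g.cell_size)
    env = make_covariates(grid, s.n_env, s.smoothness, cfg.seed)
    access = make_accessibility(grid, s.n_roads, s.n_cities, s.n_pas, cfg.seed + 1)
    cov = env.merged(access)
    pool = make_species_pool(cov, s.n_per_group, s.effect_sd, cfg.seed + 2)
    records = sample_presences(
        pool, access, s.bias_strength, s.n_records, cfg.seed + 3
    )
    mask = make_masks(grid, s.pa_fraction, s.urban_fraction, cfg.seed + 4)
    folds = assign_blocks(grid, cfg.sdm.block_size, cfg.sdm.k, cfg.seed + 5)
    kept = filter_species(records, folds, cfg.sdm.min_pixels, cfg.sdm.min_blocks)
    return World(
        grid=grid, covariates=cov, access=access, pool=pool,
        records=records, mask=mask, folds=folds, kept_species=kept,
    )


#: Reduced factor sets for quick experiments; "paper" is the full design.
_SCALE_FACTORS: dict[str, dict[str, list[str]]] = {
    "toy": {
        "surrogate": ["butterflies", "all"],
        "algorithm": ["A"],
        "bias": ["off", "on"],
        "rule": ["caz", "abf"],
        "weighting": ["none"],
        "connectivity": ["none", "high_2"],
        "pa": ["off", "on"],
    },
    "small": {
        "surrogate": ["butterflies", "reptiles", "mammals", "all"],
        "algorithm": ["A", "B"],
        "bias": ["off", "on"],
        "rule": ["caz", "abf"],
        "weighting": ["none", "redlist"],
        "connectivity": ["none", "low_1", "medium_2", "high_3"],
        "pa": ["off", "on"],
    },
    "paper": PAPER_FACTORS,
}


def design_for_scale(scale: str) -> pd.DataFrame:
    if scale not in _SCALE_FACTORS:
        raise ValueError(f"unknown scale {scale!r}")
    return build_design(_SCALE_FACTORS[scale])


@dataclass
class ExperimentResult:
    design: pd.DataFrame
    runs: pd.DataFrame
    importance: ImportanceReport
    interactions: pd.DataFrame
    summary: dict = field(default_factory=dict)


def run_sensitivity_experiment(
    cfg: RunConfig, world: World | None = None,
    prepared: PreparedInputs | None = None,
) -> ExperimentResult:
    """Build the world, prepare SDM inputs, run the factorial and attribute
    response variability to factors."""
    sens = cfg.sensitivity
    design = design_for_scale(sens.scale)
    if world is None:
        world = build_world(cfg)
    if prepared is None:
        algorithms = tuple(sorted(design["algorithm"].unique()))
        prepared = prepare_inputs(
            world.pool, world.covariates, world.records, world.folds,
            world.mask, species_ids=world.kept_species, algorithms=algorithms,
        )
    eval_stack = None
    if world is not None:
        kept = set(prepared.species_meta["species_id"])
        eval_stack = normalize_features(
            {
                sp.species_id: sp.true_intensity
                for sp in world.pool.species
                if sp.species_id in kept
            },
            world.grid,
        )
    runs = run_design(
        design, prepared, top_fractions=tuple(sens.top_fractions),
        warp=sens.warp, eval_stack=eval_stack,
    )
    varying = [c for c in design.columns if design[c].nunique() > 1]
    importance = permutation_importance(
        runs, "response_17", factors=varying,
        n_trees=sens.n_trees, n_perm=sens.n_perm, seed=cfg.seed,
    )
    interactions = interaction_mean_squares(runs, "response_17", factors=varying)

    by_bias = runs.groupby("bias")["response_17"].mean()
    summary = {
        "n_runs": int(len(runs)),
        "mean_response_17": float(runs["response_17"].mean()),
        "mean_response_17_bias_on": float(by_bias.get("on", np.nan)),
        "mean_response_17_bias_off": float(by_bias.get("off", np.nan)),
        "factor_ranking": importance.ranked_factors(),
    }
    if "response_true_17" in runs:
        by_bias_true = runs.groupby("bias")["response_true_17"].mean()
        summary["mean_response_true_17_bias_on"] = float(by_bias_true.get("on", np.nan))
        summary["mean_response_true_17_bias_off"] = float(by_bias_true.get("off", np.nan))
    return ExperimentResult(
        design=design, runs=runs, importance=importance,
        interactions=interactions, summary=summary,
    )


def run_gap_analysis(
    prepared: PreparedInputs,
    algorithm: str = "A",
    bias: str = "on",
    rule: str = "caz",
    target_fraction: float = 0.17,
    bin_width: float = 0.05,
    warp: int = 1,
) -> dict:
    """Gap analysis of the prepared world's PA network.

    Ranks the landscape ignoring PA positions (urban cells still forced
    out first), compares the ranking with the PA network, then re-ranks
    with PAs forced highest to select expansion sites up to the area
    target.
    """
    stack = prepared.stacks[(algorithm, bias)]
    free_ranking = prioritise(
        stack, rule=rule, mask=prepared.mask_pa_off, warp=warp
    )
    pa = prepared.mask_pa_on.pa_mask
    forced_ranking = prioritise(
        stack, rule=rule, mask=prepared.mask_pa_on, warp=warp
    )
    report = gap_report(
        free_ranking.rank, pa, bin_width=bin_width,
        forced_ranking=forced_ranking, target_fraction=target_fraction,
    )
    curves_free = performance_curves(free_ranking, stack)
    curves_forced = performance_curves(forced_ranking, stack)
    n_valid = prepared.grid.n_valid
    return {
        "point_biserial_r": report.point_biserial_r,
        "jaccard": report.jaccard,
        "kendall_tau": report.kendall_tau,
        "pa_fraction": float(pa.sum() / n_valid),
        "expansion_fraction": float(report.expansion_cells.sum() / n_valid),
        "representation_top_equal_area": representation_at_top(
            curves_free, float(pa.sum() / n_valid)
        ),
        "representation_in_pa": representation_at_top(
            curves_forced, float(pa.sum() / n_valid)
        ),
        "representation_expanded_17": representation_at_top(
            curves_forced, target_fraction
        ),
        "free_ranking": free_ranking,
        "forced_ranking": forced_ranking,
    }
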