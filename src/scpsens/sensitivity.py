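"""Full-factorial sensitivity analysis of the prioritisation pipeline.

The seven analysis choices a practitioner must make — surrogate taxon,
SDM algorithm, sampling-bias correction, cell-removal rule, species
weighting, connectivity option and protected-area integration — form a
factorial design (2560 combinations at the default levels). Each row is
one full prioritisation run whose response is the mean species
representation within the top 10/17/25% of the landscape. Variability in
the response is then attributed to factors with random-forest permutation
importance and to factor pairs with two-way-interaction mean squares from
a linear model.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from sklearn.ensemble import RandomForestRegressor

from .grids import GridSpec
from .prioritiser import (
    ConnectivityConfig,
    FeatureStack,
    normalize_features,
    performance_curves,
    prioritise,
    representation_at_top,
)
from .sdm import (
    FeatureSpec,
    FoldAssignment,
    PredictionStack,
    fit_ppm,
    predict_suitability,
    predictive_consistency,
    schoeners_d,
)
from .synthetic import CovariateStack, MaskLayer, SpeciesPool

logger = logging.getLogger(__name__)

__all__ = [
    "PAPER_FACTORS",
    "CONNECTIVITY_LEVELS",
    "PreparedInputs",
    "ImportanceReport",
    "build_design",
    "prepare_inputs",
    "run_design",
    "permutation_importance",
    "interaction_mean_squares",
]

#: The ten connectivity options: no connectivity plus three response
#: curves crossed with three neighbourhood radii.
CONNECTIVITY_LEVELS = ["none"] + [
    f"{curve}_{radius}"
    for curve in ("low", "medium", "high")
    for radius in (1, 2, 3)
]

#: Factor levels of the published design: 4*2*2*2*4*10*2 = 2560 runs.
PAPER_FACTORS: dict[str, list[str]] = {
    "surrogate": ["butterflies", "reptiles", "mammals", "all"],
    "algorithm": ["A", "B"],
    "bias": ["off", "on"],
    "rule": ["caz", "abf"],
    "weighting": ["none", "redlist", "consistency", "both"],
    "connectivity": CONNECTIVITY_LEVELS,
    "pa": ["off", "on"],
}

_SURROGATE_GROUP = {"butterflies": "butterfly", "reptiles": "reptile", "mammals": "mammal"}


def build_design(factors: dict[str, list[str]] | None = None) -> pd.DataFrame:
    """Cartesian product of factor levels in canonical order."""
    factors = factors if factors is not None else PAPER_FACTORS
    for name, levels in factors.items():
        if len(levels) == 0:
            raise ValueError(f"factor {name!r} has no levels")
        if len(set(levels)) != len(levels):
            raise ValueError(f"factor {name!r} has duplicate levels")
    rows = list(itertools.product(*factors.values()))
    return pd.DataFrame(rows, columns=list(factors))


def connectivity_from_level(level: str) -> ConnectivityConfig:
    if level == "none":
        return ConnectivityConfig(0, "none")
    curve, radius = level.rsplit("_", 1)
    return ConnectivityConfig(int(radius), curve)


@dataclass
class PreparedInputs:
    """Everything `run_design` needs, computed once and reused across rows.

    SDM predictions are prepared per (algorithm, bias) combination; the
    hierarchical masks exist in a PA-forcing and a no-PA variant (urban
    cells are forced out first in both).
    """

    grid: GridSpec
    species_meta: pd.DataFrame  # species_id, group, redlist_weight
    stacks: dict[tuple[str, str], FeatureStack]  # (algorithm, bias) -> stack
    consistency: dict[tuple[str, str], dict[str, float]]
    mask_pa_on: MaskLayer
    mask_pa_off: MaskLayer

    def species_for(self, surrogate: str) -> list[str]:
        if surrogate == "all":
            return list(self.species_meta["species_id"])
        group = _SURROGATE_GROUP[surrogate]
        sel = self.species_meta["group"] == group
        return list(self.species_meta.loc[sel, "species_id"])

    def weights_for(
        self, scheme: str, algorithm: str, bias: str, species: list[str]
    ) -> dict[str, float]:
        meta = self.species_meta.set_index("species_id")
        cons = self.consistency[(algorithm, bias)]
        out = {}
        for s in species:
            w = 1.0
            if scheme in ("redlist", "both"):
                w *= float(meta.loc[s, "redlist_weight"])
            if scheme in ("consistency", "both"):
                w *= max(float(cons[s]), 1e-12)
            out[s] = w
        return out


def _cv_fit_predict(
    records: pd.DataFrame,
    covariates: CovariateStack,
    folds: FoldAssignment,
    feature_spec: FeatureSpec,
    penalty: tuple[float, float],
) -> tuple[list, list[np.ndarray], list[np.ndarray], float]:
    """Fold fits plus predictions with observed and zeroed accessibility."""
    rec_fold = folds.fold_of_cells(
        records["row"].to_numpy(), records["col"].to_numpy()
    )
    fits, maps_raw, maps_corr = [], [], []
    for f in range(1, folds.k + 1):
        train = records[rec_fold != f]
        if train.empty:
            raise ValueError(f"no training presences outside fold {f}")
        fit = fit_ppm(
            train, covariates, feature_spec=feature_spec, penalty=penalty,
            use_bias_layers=True,
        )
        fits.append(fit)
        maps_raw.append(predict_suitability(fit, covariates, bias_at_zero=False))
        maps_corr.append(predict_suitability(fit, covariates, bias_at_zero=True))
    # validation log-likelihood for penalty selection (observed accessibility)
    nll = 0.0
    grid = covariates.grid
    fold_of_cell = folds.fold_raster.ravel()[grid.valid_indices()]
    for f, m in zip(range(1, folds.k + 1), maps_raw):
        mu = m.ravel()[grid.valid_indices()]
        in_fold = fold_of_cell == f
        nll += float((mu[in_fold] * grid.cell_area).sum())
        val = records[rec_fold == f]
        if not val.empty:
            mu_val = m[val["row"].to_numpy(), val["col"].to_numpy()]
            nll -= float(np.log(np.maximum(mu_val, 1e-300)).sum())
    return fits, maps_raw, maps_corr, nll


def fit_species(
    records: pd.DataFrame,
    covariates: CovariateStack,
    folds: FoldAssignment,
    algorithm: str,
    ridge_lambda: float = 1e-3,
    enet_mixing: float = 0.5,
    enet_lambdas: tuple[float, ...] = (0.3, 0.1, 0.03),
) -> dict[str, PredictionStack]:
    """Cross-validated predictions for one species under one algorithm.

    Algorithm ``A`` is a lightly-ridged log-linear model with linear and
    quadratic environmental terms (a Maxent-like model); ``B`` is an
    elastic-net-penalised model whose penalty strength is chosen by
    cross-validated predictive deviance. Returns prediction stacks keyed
    by bias level: ``"off"`` keeps the fitted accessibility effect in the
    map, ``"on"`` predicts at zero distance (bias-corrected).
    """
    spec = FeatureSpec(quadratic=True)
    if algorithm == "A":
        candidates = [(0.0, ridge_lambda)]
    elif algorithm == "B":
        candidates = [(enet_mixing, lam) for lam in enet_lambdas]
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}")
    best = None
    for penalty in candidates:
        out = _cv_fit_predict(records, covariates, folds, spec, penalty)
        if best is None or out[3] < best[1][3]:
            best = (penalty, out)
    _, (fits, maps_raw, maps_corr, _) = best
    grid = covariates.grid
    return {
        "off": PredictionStack(grid, maps_raw, np.mean(maps_raw, axis=0), False),
        "on": PredictionStack(grid, maps_corr, np.mean(maps_corr, axis=0), True),
    }


def prepare_inputs(
    pool: SpeciesPool,
    covariates: CovariateStack,
    records: pd.DataFrame,
    folds: FoldAssignment,
    mask: MaskLayer,
    species_ids: list[str] | None = None,
    algorithms: tuple[str, ...] = ("A", "B"),
) -> PreparedInputs:
    """Fit all SDM variants once and assemble the factorial's shared inputs."""
    ids = species_ids if species_ids is not None else sorted(records["species_id"].unique())
    meta = pool.metadata_frame()
    meta = meta[meta["species_id"].isin(ids)].reset_index(drop=True)

    stacks: dict[tuple[str, str], FeatureStack] = {}
    consistency: dict[tuple[str, str], dict[str, float]] = {}
    for alg in algorithms:
        per_bias_maps: dict[str, dict[str, np.ndarray]] = {"off": {}, "on": {}}
        per_bias_cons: dict[str, dict[str, float]] = {"off": {}, "on": {}}
        for sid in ids:
            rec = records[records["species_id"] == sid]
            pred = fit_species(rec, covariates, folds, alg)
            for bias in ("off", "on"):
                per_bias_maps[bias][sid] = pred[bias].mean_map
                per_bias_cons[bias][sid] = predictive_consistency(pred[bias])
        for bias in ("off", "on"):
            stacks[(alg, bias)] = normalize_features(
                per_bias_maps[bias], covariates.grid
            )
            consistency[(alg, bias)] = per_bias_cons[bias]

    levels_off = mask.levels.copy()
    levels_off[mask.pa_mask] = 1
    mask_pa_off = MaskLayer(grid=mask.grid, levels=levels_off, legend=mask.legend)
    return PreparedInputs(
        grid=covariates.grid,
        species_meta=meta,
        stacks=stacks,
        consistency=consistency,
        mask_pa_on=mask,
        mask_pa_off=mask_pa_off,
    )


def run_design(
    design: pd.DataFrame,
    prepared: PreparedInputs,
    top_fractions: tuple[float, ...] = (0.10, 0.17, 0.25),
    warp: int = 1,
    response_species: str = "run",
    eval_stack: FeatureStack | None = None,
) -> pd.DataFrame:
    """Execute one prioritisation per design row and record the responses.

    The response is the mean representation over the run's own species
    (``response_species="run"``) or over every species in the prepared
    pool (``"all"``), evaluated on the run's performance curves. If an
    ``eval_stack`` of reference (e.g. true) distributions is supplied,
    additional ``response_true_*`` columns report how much of the
    reference distributions the run's top cells capture — on synthetic
    worlds this is the representation an omniscient observer would
    measure, and is independent of the run's own possibly distorted maps.
    """
    if response_species not in ("run", "all"):
        raise ValueError("response_species must be 'run' or 'all'")
    out_rows = []
    for _, row in design.iterrows():
        key = (row["algorithm"], row["bias"])
        if key not in prepared.stacks:
            raise ValueError(f"no prepared predictions for {key} (row {dict(row)})")
        base = prepared.stacks[key]
        species = prepared.species_for(row["surrogate"])
        species = [s for s in species if s in base.species_ids]
        if not species:
            raise ValueError(f"surrogate {row['surrogate']} has no species")
        weights = prepared.weights_for(
            row["weighting"], row["algorithm"], row["bias"], species
        )
        stack = base.subset(species, weights)
        conn = connectivity_from_level(row["connectivity"])
        mask = prepared.mask_pa_on if row["pa"] == "on" else prepared.mask_pa_off
        ranking = prioritise(stack, rule=row["rule"], connectivity=conn,
                             mask=mask, warp=warp)
        if response_species == "all":
            eval_stack = base
            curves = performance_curves(ranking, base)
        else:
            curves = performance_curves(ranking, stack)
        rec = dict(row)
        for tf in top_fractions:
            rec[f"response_{int(round(tf * 100))}"] = representation_at_top(curves, tf)
        if eval_stack is not None:
            ids = [s for s in (species if response_species == "run"
                               else base.species_ids)
                   if s in eval_stack.species_ids]
            true_curves = performance_curves(ranking, eval_stack.subset(ids))
            for tf in top_fractions:
                rec[f"response_true_{int(round(tf * 100))}"] = representation_at_top(
                    true_curves, tf
                )
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


@dataclass
class ImportanceReport:
    """Permutation importances and two-way interaction mean squares."""

    importances: pd.DataFrame  # factor, importance_mean, importance_sd
    interactions: pd.DataFrame | None = None

    def ranked_factors(self) -> list[str]:
        return list(self.importances.sort_values(
            "importance_mean", ascending=False)["factor"])


def permutation_importance(
    table: pd.DataFrame,
    response: str = "response_17",
    factors: list[str] | None = None,
    n_trees: int = 500,
    n_perm: int = 10,
    seed: int = 0,
) -> ImportanceReport:
    """Random-forest permutation importance of each factor for the response.

    A regression forest is cross-fitted (two seeded halves); the
    importance of a factor is the mean increase in held-out mean squared
    error when its column is permuted, averaged over ``n_perm``
    permutation replicates and both halves.
    """
    if factors is None:
        factors = [c for c in table.columns if not c.startswith("response")]
    if len(table) < 2:
        raise ValueError("need at least two runs")
    y = table[response].to_numpy(dtype=np.float64)
    if np.unique(y).size < 1:
        raise ValueError("empty response")
    X = np.column_stack(
        [pd.factorize(table[f], sort=True)[0] for f in factors]
    ).astype(np.float64)
    rng = np.random.default_rng(seed)
    n = len(table)
    perm_idx = rng.permutation(n)
    halves = (perm_idx[: n // 2], perm_idx[n // 2:])
    inc = np.zeros((len(factors), 2 * n_perm))
    for h, (train, test) in enumerate(((halves[0], halves[1]), (halves[1], halves[0]))):
        forest = RandomForestRegressor(
            n_estimators=n_trees, random_state=int(rng.integers(2**31)), n_jobs=1
        )
        forest.fit(X[train], y[train])
        base_mse = float(np.mean((forest.predict(X[test]) - y[test]) ** 2))
        for j in range(len(factors)):
            for p in range(n_perm):
                Xp = X[test].copy()
                Xp[:, j] = Xp[rng.permutation(test.size), j]
                mse = float(np.mean((forest.predict(Xp) - y[test]) ** 2))
                inc[j, h * n_perm + p] = mse - base_mse
    imp = pd.DataFrame(
        {
            "factor": factors,
            "importance_mean": inc.mean(axis=1),
            "importance_sd": inc.std(axis=1, ddof=1),
        }
    ).sort_values("importance_mean", ascending=False, ignore_index=True)
    return ImportanceReport(importances=imp)


def interaction_mean_squares(
    table: pd.DataFrame,
    response: str = "response_17",
    factors: list[str] | None = None,
) -> pd.DataFrame:
    """ANOVA mean squares of all two-way factor interactions, ranked.

    Fits a linear model with all main effects and first-order
    interactions. On a balanced (full-factorial) design the terms are
    orthogonal and the decomposition is order-independent; unbalanced
    tables are processed with a warning.
    """
    if factors is None:
        factors = [c for c in table.columns if not c.startswith("response")]
    factors = [f for f in factors if table[f].nunique() > 1]
    counts = table.groupby(factors, observed=True).size()
    if counts.nunique() > 1:
        logger.warning(
            "design is unbalanced; interaction sums of squares depend on term order"
        )
    df = table[factors].copy()
    df["_y"] = table[response].to_numpy()
    terms = " + ".join(f"C({f})" for f in factors)
    pairs = " + ".join(
        f"C({a}):C({b})" for a, b in itertools.combinations(factors, 2)
    )
    formula = f"_y ~ {terms}" + (f" + {pairs}" if pairs else "")
    fit = smf.ols(formula, data=df).fit()
    anova = sm.stats.anova_lm(fit, typ=1)
    anova = anova.rename_axis("term").reset_index()
    anova["mean_sq"] = anova["sum_sq"] / anova["df"]
    out = anova[anova["term"].str.contains(":")][["term", "df", "sum_sq", "mean_sq"]]
    out = out.sort_values("mean_sq", ascending=False, ignore_index=True)
    out["term"] = (
        out["term"].str.replace(r"C\((\w+)\)", r"\1", regex=True)
    )
    return out
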