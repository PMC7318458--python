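import numpy as np
import pytest

from scpsens.grids import GridSpec
from scpsens import synthetic as syn
from scpsens.prioritiser import FeatureStack
from scpsens.sdm import assign_blocks, filter_species
from scpsens.sensitivity import prepare_inputs


@pytest.fixture(scope="session")
def grid10():
    return GridSpec(10, 10)


@pytest.fixture(scope="session")
def small_world():
    """A 24x24 landscape with 9 species and biased samples, shared read-only."""
    grid = GridSpec(24, 24)
    env = syn.make_covariates(grid, 2, 3.0, seed=101)
    access = syn.make_accessibility(grid, 2, 3, 2, seed=102)
    cov = env.merged(access)
    pool = syn.make_species_pool(
        cov, {"butterfly": 3, "reptile": 3, "mammal": 3}, effect_sd=0.8, seed=103
    )
    records = syn.sample_presences(pool, access, 0.3, n_records=80, seed=104)
    mask = syn.make_masks(grid, 0.15, 0.05, seed=105)
    folds = assign_blocks(grid, block_size=4, k=5, seed=106)
    kept = filter_species(records, folds)
    return {
        "grid": grid, "cov": cov, "access": access, "pool": pool,
        "records": records, "mask": mask, "folds": folds, "kept": kept,
    }


@pytest.fixture(scope="session")
def small_prepared(small_world):
    """Prepared factorial inputs (algorithm A only) for the small world."""
    w = small_world
    return prepare_inputs(
        w["pool"], w["cov"], w["records"], w["folds"], w["mask"],
        species_ids=w["kept"], algorithms=("A",),
    )


def random_stack(grid, n_species, seed, weights=None):
    """A random normalised feature stack for engine tests."""
    rng = np.random.default_rng(seed)
    Q = rng.random((grid.n_valid, n_species)) ** 2
    Q /= Q.sum(axis=0)
    w = np.ones(n_species) if weights is None else np.asarray(weights, float)
    return FeatureStack(
        grid=grid, species_ids=[f"s{j}" for j in range(n_species)], Q=Q, weights=w
    )
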