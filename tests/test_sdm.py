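"""Point-process SDM stage: folds, filtering, DWPR fits, consistency."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from scpsens.grids import GridSpec
from scpsens import synthetic as syn
from scpsens.sdm import (
    FeatureSpec,
    PredictionStack,
    assign_blocks,
    cross_validate,
    filter_species,
    fit_ppm,
    predict_suitability,
    predictive_consistency,
    schoeners_d,
)


class TestAssignBlocks:
    def test_exact_tiling_one_block_per_fold(self, grid10):
        folds = assign_blocks(grid10, block_size=5, k=4, seed=0)
        assert folds.n_blocks == 4
        assert sorted(folds.fold_of_block) == [1, 2, 3, 4]

    def test_fold_balance_within_one_block(self):
        grid = GridSpec(30, 30)
        folds = assign_blocks(grid, block_size=4, k=5, seed=1)
        sizes = np.bincount(folds.fold_of_block)[1:]
        assert sizes.max() - sizes.min() <= 1

    def test_deterministic(self, grid10):
        a = assign_blocks(grid10, 2, 5, seed=3)
        b = assign_blocks(grid10, 2, 5, seed=3)
        np.testing.assert_array_equal(a.fold_of_block, b.fold_of_block)

    def test_too_few_blocks_rejected(self, grid10):
        with pytest.raises(ValueError):
            assign_blocks(grid10, block_size=10, k=5, seed=0)


@pytest.fixture(scope="module")
def folds():
    return assign_blocks(GridSpec(20, 20), block_size=4, k=5, seed=0)


class TestFilterSpecies:

    @staticmethod
    def records_for(folds, n_cells, n_blocks, species="sp"):
        """n_cells unique cells spread over exactly n_blocks blocks."""
        rows, cols = [], []
        wanted_blocks = np.unique(folds.block_id[folds.block_id >= 0])[:n_blocks]
        i = 0
        while len(rows) < n_cells:
            blk = wanted_blocks[i % n_blocks]
            rr, cc = np.nonzero(folds.block_id == blk)
            j = (i // n_blocks) % rr.size
            if (rr[j], cc[j]) not in set(zip(rows, cols)):
                rows.append(rr[j])
                cols.append(cc[j])
            i += 1
        return pd.DataFrame({"species_id": species, "row": rows, "col": cols})

    @pytest.mark.parametrize(
        "n_cells,n_blocks,kept",
        [
            (8, 5, True),   # just enough pixels and blocks
            (7, 5, False),  # too few unique pixels
            (20, 3, False), # plenty of pixels but too few blocks for 5-fold CV
        ],
    )
    def test_retention_rule(self, folds, n_cells, n_blocks, kept):
        rec = self.records_for(folds, n_cells, n_blocks)
        assert (filter_species(rec, folds) == ["sp"]) is kept

    def test_duplicate_records_do_not_inflate_pixels(self, folds):
        rec = self.records_for(folds, 7, 5)
        rec = pd.concat([rec, rec.head(3)], ignore_index=True)
        assert filter_species(rec, folds) == []

    def test_empty_table(self, folds):
        assert filter_species(pd.DataFrame(columns=["species_id", "row", "col"]), folds) == []


def _sample_cells(grid, intensity, n, seed):
    p = intensity[grid.valid_mask]
    idx = np.random.default_rng(seed).choice(
        grid.valid_indices(), size=n, p=p / p.sum()
    )
    r, c = np.unravel_index(idx, grid.shape)
    return pd.DataFrame({"species_id": "sp", "row": r, "col": c})


@pytest.fixture(scope="module")
def cov():
    return syn.make_covariates(GridSpec(30, 30), 2, 3.0, seed=42)


class TestFitPPM:

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_coefficient_recovery(self, cov, seed):
        # truth: log-intensity = 1.0*x1 - 0.5*x2; estimates within 3 SE
        grid = cov.grid
        eta = 1.0 * cov.env[0] - 0.5 * cov.env[1]
        rec = _sample_cells(grid, np.exp(eta), 2000, seed)
        fit = fit_ppm(rec, cov, FeatureSpec(quadratic=False))
        est = fit.coef_table()
        for name, truth in (("env_0", 1.0), ("env_1", -0.5)):
            i = ["intercept", *fit.feature_names].index(name)
            assert abs(est[name] - truth) < 3 * fit.bse[i]

    def test_huge_penalty_shrinks_all_slopes(self, cov):
        rec = _sample_cells(cov.grid, np.exp(cov.env[0]), 500, 9)
        fit = fit_ppm(rec, cov, penalty=(0.0, 1e6))
        assert np.abs(fit.coefficients[1:]).max() < 1e-6

    def test_interceptonly_matches_point_count(self, cov):
        # Poisson point-process identity: total predicted intensity = n
        grid = cov.grid
        n = 800
        rec = _sample_cells(grid, np.ones(grid.shape), n, 5)
        fit = fit_ppm(rec, cov, FeatureSpec(env_layers=(), quadratic=False))
        total = np.nansum(predict_suitability(fit, cov)) * grid.cell_area
        assert abs(total - n) / n < 0.01

    def test_zero_presences_rejected(self, cov):
        with pytest.raises(ValueError):
            fit_ppm(pd.DataFrame(columns=["species_id", "row", "col"]), cov)


class TestPredictSuitability:
    def test_constant_model_gives_constant_map(self):
        cov = syn.make_covariates(GridSpec(8, 8), 1, 1.0, seed=0)
        rec = _sample_cells(cov.grid, np.ones(cov.grid.shape), 50, 1)
        fit = fit_ppm(rec, cov, FeatureSpec(env_layers=(), quadratic=False))
        m = predict_suitability(fit, cov)
        c = np.exp(fit.coefficients[0])
        np.testing.assert_allclose(m[cov.grid.valid_mask], c, rtol=1e-12)

    def test_zero_access_coefficients_make_correction_a_noop(self):
        grid = GridSpec(15, 15)
        env = syn.make_covariates(grid, 1, 2.0, seed=3)
        access = syn.make_accessibility(grid, 1, 1, 0, seed=4)
        cov = env.merged(access)
        rec = _sample_cells(grid, np.exp(env.env[0]), 300, 5)
        fit = fit_ppm(rec, cov, use_bias_layers=True)
        fit.coefficients[-len(fit.access_names):] = 0.0
        raw = predict_suitability(fit, cov, bias_at_zero=False)
        corr = predict_suitability(fit, cov, bias_at_zero=True)
        np.testing.assert_array_equal(raw, corr)

    def test_corrected_map_free_of_accessibility_signal(self):
        # partial correlation with access layers given env features ~ 0
        grid = GridSpec(30, 30)
        env = syn.make_covariates(grid, 2, 3.0, seed=6)
        access = syn.make_accessibility(grid, 2, 2, 1, seed=7)
        cov = env.merged(access)
        pool = syn.make_species_pool(cov, {"mammal": 1}, 0.8, seed=8)
        rec = syn.sample_presences(pool, access, 0.5, n_records=2000, seed=9)
        fit = fit_ppm(rec, cov, use_bias_layers=True, penalty=(0.0, 1e-4))
        corr = predict_suitability(fit, cov, bias_at_zero=True)
        raw = predict_suitability(fit, cov, bias_at_zero=False)
        valid = grid.valid_mask
        Xenv = np.column_stack(
            [np.ones(grid.n_valid)]
            + [e[valid] for e in cov.env]
            + [e[valid] ** 2 for e in cov.env]
        )

        def partial_r(log_map, a):
            resid = log_map - Xenv @ np.linalg.lstsq(Xenv, log_map, rcond=None)[0]
            ra = a - Xenv @ np.linalg.lstsq(Xenv, a, rcond=None)[0]
            if resid.std() < 1e-10 * log_map.std():
                return 0.0  # map is a function of env alone
            return np.corrcoef(resid, ra)[0, 1]

        rs_corr = [partial_r(np.log(corr[valid]), a[valid]) for a in cov.access]
        rs_raw = [partial_r(np.log(raw[valid]), a[valid]) for a in cov.access]
        assert max(abs(r) for r in rs_corr) < 0.05
        # the uncorrected map retains a real accessibility signal
        assert max(abs(r) for r in rs_raw) > 0.3


@pytest.fixture(scope="module")
def cv_setup():
    grid = GridSpec(20, 20)
    cov = syn.make_covariates(grid, 2, 2.0, seed=20)
    folds = assign_blocks(grid, block_size=4, k=5, seed=21)
    rec = _sample_cells(grid, np.exp(cov.env[0]), 300, 22)
    return cov, folds, rec


class TestCrossValidate:

    def test_mean_is_cellwise_mean_of_folds(self, cv_setup):
        cov, folds, rec = cv_setup
        stack = cross_validate(rec, cov, folds)
        np.testing.assert_allclose(
            stack.mean_map, np.mean(stack.fold_maps, axis=0), atol=1e-12
        )
        assert stack.k == 5

    def test_single_fold_rejected(self, cv_setup):
        cov, _, _ = cv_setup
        with pytest.raises(ValueError):
            assign_blocks(cov.grid, block_size=4, k=1, seed=0)

    def test_whole_grid_block_rejected(self, cv_setup):
        cov, _, _ = cv_setup
        with pytest.raises(ValueError):
            assign_blocks(cov.grid, block_size=20, k=5, seed=0)

    def test_empty_training_fold_is_named(self, cv_setup):
        cov, folds, rec = cv_setup
        # all records inside fold 1's blocks -> training for fold 1 is empty
        in_fold1 = folds.fold_raster == 1
        rr, cc = np.nonzero(in_fold1)
        rec1 = pd.DataFrame({"species_id": "sp", "row": rr[:20], "col": cc[:20]})
        with pytest.raises(ValueError, match="fold 1"):
            cross_validate(rec1, cov, folds)


class TestSchoenersD:
    def test_identical_maps(self):
        p = np.array([[0.2, 0.8], [1.5, 0.5]])
        assert schoeners_d(p, 3.7 * p) == pytest.approx(1.0)

    def test_disjoint_supports(self):
        p = np.array([1.0, 0.0, 2.0, 0.0])
        q = np.array([0.0, 3.0, 0.0, 1.0])
        assert schoeners_d(p, q) == pytest.approx(0.0)

    def test_half_overlap(self):
        assert schoeners_d(np.array([0.5, 0.5]), np.array([1.0, 0.0])) == pytest.approx(0.5)

    def test_zero_sum_rejected(self):
        with pytest.raises(ValueError):
            schoeners_d(np.zeros(4), np.ones(4))


class TestPredictiveConsistency:
    @staticmethod
    def stack_from(maps):
        return PredictionStack(
            grid=GridSpec(*maps[0].shape),
            fold_maps=list(maps),
            mean_map=np.mean(maps, axis=0),
            bias_corrected=False,
        )

    def test_five_folds_average_the_ten_pairs(self):
        rng = np.random.default_rng(0)
        maps = [rng.random((4, 4)) for _ in range(5)]
        stack = self.stack_from(maps)
        pairs = [schoeners_d(a, b) for a, b in combinations(maps, 2)]
        assert len(pairs) == 10
        assert predictive_consistency(stack) == pytest.approx(np.mean(pairs))

    def test_identical_folds_score_one(self):
        m = np.random.default_rng(1).random((4, 4))
        assert predictive_consistency(self.stack_from([m] * 5)) == pytest.approx(1.0)

    def test_two_folds_equal_single_d(self):
        rng = np.random.default_rng(2)
        a, b = rng.random((4, 4)), rng.random((4, 4))
        assert predictive_consistency(self.stack_from([a, b])) == pytest.approx(
            schoeners_d(a, b)
        )

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        maps = [rng.random((4, 4)) for _ in range(4)]
        base = predictive_consistency(self.stack_from(maps))
        maps[2] = maps[2] * 123.0
        assert predictive_consistency(self.stack_from(maps)) == pytest.approx(base)
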