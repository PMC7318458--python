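"""Greedy engine: marginal-loss rules, connectivity, masks, curves."""

import logging

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpsens.grids import GridSpec
from scpsens.prioritiser import (
    ConnectivityConfig,
    FeatureStack,
    abf_marginal_losses,
    bqp_factor,
    caz_marginal_losses,
    normalize_features,
    performance_curves,
    prioritise,
    representation_at_top,
    retention_raster,
)
from scpsens.synthetic import MaskLayer, make_masks

from .conftest import random_stack
from .oracles import mean_nn_distance, naive_removal_order


def two_cell_stack():
    """2 valid cells, 2 species: q = A:(0.7, 0.2), B:(0.3, 0.8)."""
    mask = np.zeros((2, 2), dtype=bool)
    mask[0, 0] = mask[0, 1] = True
    grid = GridSpec(2, 2, valid_mask=mask)
    Q = np.array([[0.7, 0.2], [0.3, 0.8]])
    return FeatureStack(grid, ["s1", "s2"], Q, np.ones(2))


class TestNormalizeFeatures:
    def test_constant_species_is_uniform(self, grid10):
        stack = normalize_features({"sp": np.full(grid10.shape, 3.3)}, grid10)
        np.testing.assert_allclose(stack.Q, 1.0 / grid10.n_valid)

    def test_scale_invariance(self, grid10):
        r = np.random.default_rng(0).random(grid10.shape)
        a = normalize_features({"sp": r}, grid10)
        b = normalize_features({"sp": 10 * r}, grid10)
        np.testing.assert_allclose(a.Q, b.Q)

    def test_two_cell_fractions(self):
        mask = np.array([[True, True], [False, False]])
        grid = GridSpec(2, 2, valid_mask=mask)
        raster = np.array([[0.7, 0.3], [np.nan, np.nan]])
        stack = normalize_features({"sp": raster}, grid)
        np.testing.assert_allclose(stack.Q[:, 0], [0.7, 0.3])

    def test_all_zero_species_named(self, grid10):
        with pytest.raises(ValueError, match="dead_sp"):
            normalize_features({"dead_sp": np.zeros(grid10.shape)}, grid10)


class TestMarginalLosses:
    def test_caz_toy_values_and_order(self):
        stack = two_cell_stack()
        f = np.ones(2)
        delta = caz_marginal_losses(stack.Q, stack.weights, f,
                                    stack.Q.sum(0), np.array([0, 1]))
        np.testing.assert_allclose(delta, [0.7, 0.8])
        order = prioritise(stack, "caz").order
        assert order[0] == 0  # cell A (lower max fraction) removed first

    def test_caz_linear_in_weight(self):
        stack = two_cell_stack()
        f = np.ones(2)
        base = caz_marginal_losses(stack.Q, np.array([1.0, 1.0]), f,
                                   stack.Q.sum(0), np.array([0, 1]))
        double = caz_marginal_losses(stack.Q, np.array([1.0, 2.0]), f,
                                     stack.Q.sum(0), np.array([0, 1]))
        # species 2 is the arg-max for both cells here
        np.testing.assert_allclose(double[1], 2 * base[1])

    def test_abf_linear_limit_is_weighted_sum(self):
        stack = two_cell_stack()
        f = np.ones(2)
        w = np.array([2.0, 3.0])
        delta = abf_marginal_losses(stack.Q, w, f, stack.Q.sum(0),
                                    np.array([0, 1]), z=1.0)
        np.testing.assert_allclose(delta, stack.Q @ w)

    def test_abf_toy_values(self):
        # independent arithmetic: delta_i = sum_j [1 - (1 - q_ij)^0.25]
        stack = two_cell_stack()
        delta = abf_marginal_losses(stack.Q, stack.weights, np.ones(2),
                                    stack.Q.sum(0), np.array([0, 1]), z=0.25)
        expected = [
            sum(1.0 - (1.0 - q) ** 0.25 for q in row) for row in stack.Q
        ]
        np.testing.assert_allclose(delta, expected)
        np.testing.assert_allclose(delta, [0.31418, 0.41657], atol=1e-4)
        assert prioritise(stack, "abf").order[0] == 0

    def test_zero_suitability_cell_costs_nothing(self):
        grid = GridSpec(2, 2)
        Q = np.array([[0.5, 0.0], [0.5, 0.6], [0.0, 0.4], [0.0, 0.0]])
        stack = FeatureStack(grid, ["a", "b"], Q, np.ones(2))
        for rule, fn in (("caz", caz_marginal_losses),):
            delta = fn(Q, stack.weights, np.ones(4), Q.sum(0), np.arange(4))
            assert delta[3] == 0.0
        assert prioritise(stack, "abf").order[0] == 3


class TestNeighbourhood:
    def test_full_and_empty_retention(self, grid10):
        all_in = np.ones(grid10.shape, dtype=bool)
        np.testing.assert_allclose(retention_raster(grid10, all_in, 1), 1.0)
        none_in = np.zeros(grid10.shape, dtype=bool)
        rho = retention_raster(grid10, none_in, 2)
        np.testing.assert_allclose(rho, 0.0)

    def test_half_neighbourhood(self):
        grid = GridSpec(3, 3)
        remaining = np.ones((3, 3), dtype=bool)
        remaining[0, :] = False
        remaining[1, 0] = False  # centre cell loses 4 of its 8 neighbours
        rho = retention_raster(grid, remaining, 1)
        assert rho[1, 1] == pytest.approx(0.5)

    def test_isolated_cell_defaults_to_one(self):
        mask = np.zeros((5, 5), dtype=bool)
        mask[0, 0] = True
        mask[4, 4] = True
        mask[4, 3] = True
        mask[0, 1] = True
        grid = GridSpec(5, 5, valid_mask=mask)
        lonely = np.zeros((5, 5), dtype=bool)
        lonely[0, 0] = True
        grid2 = GridSpec(5, 5, valid_mask=lonely | (np.indices((5, 5)).sum(0) == 8))
        rho = retention_raster(grid2, grid2.valid_mask, 1)
        assert rho[0, 0] == 1.0  # no valid neighbour at all

    @pytest.mark.parametrize(
        "rho,curve,expected",
        [(1.0, "high", 1.0), (0.3, "none", 1.0), (0.5, "medium", 0.7),
         (0.0, "high", 0.0), (0.5, "low", 0.875)],
    )
    def test_bqp_factor_curves(self, rho, curve, expected):
        assert bqp_factor(rho, curve) == pytest.approx(expected)


class TestPrioritise:
    def test_uniform_species_removes_row_major(self, grid10):
        stack = normalize_features({"sp": np.ones(grid10.shape)}, grid10)
        ranking = prioritise(stack, "caz")
        np.testing.assert_array_equal(ranking.order, grid10.valid_indices())
        ranks = np.sort(ranking.rank[grid10.valid_mask])
        np.testing.assert_allclose(
            ranks, np.arange(1, grid10.n_valid + 1) / grid10.n_valid
        )

    @pytest.mark.parametrize("rule", ["caz", "abf"])
    def test_oracle_equivalence_quick(self, rule):
        grid = GridSpec(6, 6)
        stack = random_stack(grid, 3, seed=17)
        conn = ConnectivityConfig(1, "medium")
        got = prioritise(stack, rule, conn).order
        expected = naive_removal_order(stack, rule, "medium", 1)
        np.testing.assert_array_equal(got, expected)

    def test_mask_strata_are_strict(self):
        grid = GridSpec(12, 12)
        stack = random_stack(grid, 3, seed=5)
        mask = make_masks(grid, 0.2, 0.15, seed=6)
        ranking = prioritise(stack, "caz", mask=mask)
        r = ranking.rank
        assert r[mask.pa_mask].min() > r[mask.levels == 1].max()
        assert r[mask.levels == 1].min() > r[mask.urban_mask].max()

    def test_nested_top_sets(self):
        grid = GridSpec(12, 12)
        ranking = prioritise(random_stack(grid, 4, seed=9), "abf")
        for f1, f2 in ((0.05, 0.10), (0.10, 0.17), (0.17, 0.25)):
            assert not (ranking.top_mask(f1) & ~ranking.top_mask(f2)).any()

    def test_warp_approximation_and_validation(self, caplog):
        grid = GridSpec(10, 10)
        stack = random_stack(grid, 3, seed=2)
        with pytest.raises(ValueError):
            prioritise(stack, "caz", warp=0)
        with caplog.at_level(logging.WARNING):
            ranking = prioritise(stack, "caz", warp=1000)
        assert "capped" in caplog.text
        assert np.array_equal(np.sort(ranking.order), grid.valid_indices())

    @pytest.mark.parametrize("seed", range(10))
    def test_connectivity_aggregates_and_costs_representation(self, seed):
        # high response curve -> more clumped top set, lower representation
        grid = GridSpec(15, 15)
        stack = random_stack(grid, 3, seed=100 + seed)
        r_none = prioritise(stack, "caz")
        r_high = prioritise(stack, "caz", ConnectivityConfig(2, "high"))
        nn_none = mean_nn_distance(r_none.top_mask(0.17))
        nn_high = mean_nn_distance(r_high.top_mask(0.17))
        rep_none = representation_at_top(performance_curves(r_none, stack), 0.17)
        rep_high = representation_at_top(performance_curves(r_high, stack), 0.17)
        assert nn_high <= nn_none + 1e-12
        assert rep_high <= rep_none + 1e-12


class TestPerformanceCurves:
    def test_endpoints_and_monotonicity(self):
        grid = GridSpec(9, 9)
        stack = random_stack(grid, 4, seed=3)
        curves = performance_curves(prioritise(stack, "caz"), stack)
        np.testing.assert_allclose(curves.representation[0], 1.0)
        np.testing.assert_allclose(curves.representation[-1], 0.0, atol=1e-12)
        assert (np.diff(curves.representation, axis=0) <= 1e-12).all()
        assert curves.mean_curve[0] == pytest.approx(1.0)

    def test_uniform_species_representation_is_area(self):
        grid = GridSpec(10, 10)
        stack = normalize_features({"sp": np.ones(grid.shape)}, grid)
        curves = performance_curves(prioritise(stack, "abf"), stack)
        assert representation_at_top(curves, 0.17) == pytest.approx(0.17, abs=0.01)

    def test_full_landscape_representation_is_one(self):
        grid = GridSpec(8, 8)
        stack = random_stack(grid, 2, seed=1)
        curves = performance_curves(prioritise(stack, "caz"), stack)
        assert representation_at_top(curves, 1.0) == 1.0

    def test_unknown_species_rejected(self):
        grid = GridSpec(8, 8)
        stack = random_stack(grid, 2, seed=1)
        ranking = prioritise(stack, "caz")
        with pytest.raises(ValueError):
            performance_curves(ranking, stack, ["nope"])


@settings(max_examples=20, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), n_species=st.integers(1, 5))
def test_rank_raster_is_a_nested_permutation(seed, n_species):
    grid = GridSpec(7, 7)
    stack = random_stack(grid, n_species, seed=seed)
    ranking = prioritise(stack, "caz")
    ranks = np.sort(ranking.rank[grid.valid_mask])
    np.testing.assert_allclose(ranks, np.arange(1, 50) / 49.0)


def test_connectivity_config_validation():
    with pytest.raises(ValueError):
        ConnectivityConfig(0, "high")
    with pytest.raises(ValueError):
        ConnectivityConfig(2, "none")
    with pytest.raises(ValueError):
        ConnectivityConfig(4, "low")
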