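"""Exact LOO tables, the stacking objective, and simplex optimization."""

import math

import numpy as np
import pytest
from scipy import integrate, stats

from bernstack import (
    BetaIntervalModel,
    BinaryOutcomeData,
    ModelSet,
    PointMassModel,
    ZeroProbabilityError,
    combined_loo_density,
    loo_predictive_table,
    optimize_stacking_weights,
    stacking_objective,
    stacking_posterior_density,
    stacking_predictive,
)
from conftest import simplex_grid_search


def refit_loo_predictive(model: BetaIntervalModel, reduced: BinaryOutcomeData, value: int) -> float:
    """Refit oracle: rebuild the truncated posterior on the reduced data by
    numerical integration and evaluate its predictive for the held-out value."""
    a, b, lo, hi = model.base_a, model.base_b, model.lower, model.upper

    def post_unnorm(t):
        return t**reduced.s * (1 - t) ** reduced.f * stats.beta.pdf(t, a, b)

    z, _ = integrate.quad(post_unnorm, lo, hi, epsabs=1e-14, epsrel=1e-12, limit=200)
    mean, _ = integrate.quad(
        lambda t: t * post_unnorm(t) / z, lo, hi, epsabs=1e-14, epsrel=1e-12, limit=200
    )
    return mean if value == 1 else 1.0 - mean


class TestLOOTable:
    def test_three_interval_table_reproduces_printed_row(self, three_interval_table):
        assert np.round(three_interval_table.q0, 4).tolist() == [0.7758, 0.4786, 0.2206]

    def test_held_out_one_row_mirrors_held_out_zero(self, three_interval_table):
        assert three_interval_table.q1 == pytest.approx(
            three_interval_table.q0[::-1], abs=1e-12
        )

    def test_requires_at_least_two_observations(self, three_interval_set):
        with pytest.raises(ValueError, match="at least 2"):
            loo_predictive_table(three_interval_set, BinaryOutcomeData(s=1, f=0))

    def test_absent_value_marked_not_applicable(self):
        ms = ModelSet([BetaIntervalModel(1, 1)], prior_probs=[1.0])
        table = loo_predictive_table(ms, BinaryOutcomeData(s=4, f=0))
        assert np.isnan(table.q0[0]) and not table.q0_defined[0]
        assert table.q1_defined[0]

    def test_undefined_conditional_flagged_with_warning(self):
        ms = ModelSet([PointMassModel(1.0), BetaIntervalModel(1, 1)], prior_probs=[0.5, 0.5])
        with pytest.warns(UserWarning, match="undefined"):
            table = loo_predictive_table(ms, BinaryOutcomeData(s=9, f=1))
        # removing a success leaves the failure: reduced data impossible under theta=1
        assert not table.q1_defined[0]
        # removing the single failure leaves all successes: q0 defined (and 0)
        assert table.q0_defined[0] and table.q0[0] == 0.0
        assert not table.stackable()[0] and table.stackable()[1]

    def test_marginal_ratio_equals_explicit_refit(self):
        """The one-line marginal-likelihood ratio must equal refitting the
        truncated posterior on the reduced data, over randomized cases."""
        rng = np.random.default_rng(11)
        for _ in range(8):
            a, b = rng.uniform(0.5, 4.0, size=2)
            lo, hi = np.sort(rng.uniform(0.0, 1.0, size=2))
            if hi - lo < 0.1:
                hi = min(1.0, lo + 0.1)
            model = BetaIntervalModel(a, b, lo, hi)
            s = int(rng.integers(1, 13))
            f = int(rng.integers(1, 13))
            data = BinaryOutcomeData(s=s, f=f)
            table = loo_predictive_table([model], data)
            assert table.q0[0] == pytest.approx(
                refit_loo_predictive(model, data.remove(0), 0), abs=1e-12
            )
            assert table.q1[0] == pytest.approx(
                refit_loo_predictive(model, data.remove(1), 1), abs=1e-12
            )


class TestCombinedDensityAndObjective:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            ((0.5, 0.0, 0.5), 0.4982),
            ((0.0, 1.0, 0.0), 0.4786),
            ((1 / 3, 1 / 3, 1 / 3), 0.4917),
        ],
    )
    def test_combined_density_printed_values(self, three_interval_table, weights, expected):
        for value in (0, 1):
            got = combined_loo_density(weights, three_interval_table, value)
            assert round(got, 4) == expected

    def test_positive_weight_on_undefined_entry_raises(self):
        ms = ModelSet([PointMassModel(1.0), BetaIntervalModel(1, 1)], prior_probs=[0.5, 0.5])
        with pytest.warns(UserWarning):
            table = loo_predictive_table(ms, BinaryOutcomeData(s=9, f=1))
        with pytest.raises(ZeroProbabilityError):
            combined_loo_density((0.5, 0.5), table, 1)

    def test_objective_at_symmetric_optimum(self, three_interval_table):
        got = stacking_objective((0.5, 0.0, 0.5), three_interval_table)
        c = combined_loo_density((0.5, 0.0, 0.5), three_interval_table, 0)
        assert got == pytest.approx(math.log(c), abs=1e-12)

    def test_ordering_of_candidate_weights(self, three_interval_table):
        best = stacking_objective((0.5, 0.0, 0.5), three_interval_table)
        middle_only = stacking_objective((0.0, 1.0, 0.0), three_interval_table)
        equal = stacking_objective((1 / 3, 1 / 3, 1 / 3), three_interval_table)
        assert best > equal > middle_only

    def test_objective_depends_only_on_data_composition(self, three_interval_table):
        """Replicating the data composition leaves the objective (an average)
        and hence the maximizing weights unchanged."""
        w = (0.3, 0.3, 0.4)
        base = stacking_objective(w, three_interval_table)
        replicated = stacking_objective(
            w, three_interval_table, BinaryOutcomeData(s=50, f=50)
        )
        assert replicated == pytest.approx(base, abs=1e-12)


class TestOptimizer:
    def test_three_interval_optimum_splits_between_mirrored_models(
        self, three_interval_table
    ):
        sol = optimize_stacking_weights(three_interval_table)
        assert sol.converged
        assert sol.weights == pytest.approx([0.5, 0.0, 0.5], abs=1e-3)
        assert sol.weights[1] == 0.0  # snapped exactly

    def test_singleton_model_gets_weight_one(self):
        table = loo_predictive_table(
            [BetaIntervalModel(1, 1)], BinaryOutcomeData(s=3, f=2)
        )
        sol = optimize_stacking_weights(table)
        assert sol.weights == pytest.approx([1.0])

    @pytest.mark.parametrize("n", [2, 5, 10, 100])
    def test_general_law_takes_all_weight_under_all_successes(self, n):
        """With n all-success observations the point mass at theta = 1 gets
        stacking weight 1, for every n."""
        ms = ModelSet(
            [PointMassModel(1.0), BetaIntervalModel(1, 1)], prior_probs=[0.5, 0.5]
        )
        table = loo_predictive_table(ms, BinaryOutcomeData(s=n, f=0))
        sol = optimize_stacking_weights(table)
        assert sol.weights[0] == pytest.approx(1.0, abs=1e-3)

    def test_matches_dense_grid_search_on_fixtures(self, three_interval_table):
        sol = optimize_stacking_weights(three_interval_table)
        w_grid, obj_grid = simplex_grid_search(
            three_interval_table.q0,
            three_interval_table.q1,
            three_interval_table.s,
            three_interval_table.f,
        )
        assert sol.weights == pytest.approx(w_grid, abs=1e-3)
        assert sol.objective_value >= obj_grid - 1e-8

    def test_matches_grid_search_on_asymmetric_case(self):
        models = [
            BetaIntervalModel(1, 1, 0.0, 0.4, label="low"),
            BetaIntervalModel(1, 1, 0.4, 1.0, label="high"),
        ]
        table = loo_predictive_table(models, BinaryOutcomeData(s=13, f=7))
        sol = optimize_stacking_weights(table)
        w_grid, obj_grid = simplex_grid_search(table.q0, table.q1, table.s, table.f)
        assert sol.weights == pytest.approx(w_grid, abs=1e-3)
        assert sol.objective_value >= obj_grid - 1e-8

    def test_duplicated_model_flags_flat_optimum(self):
        models = [
            BetaIntervalModel(1, 1, label="u1"),
            BetaIntervalModel(1, 1, label="u2"),
        ]
        table = loo_predictive_table(models, BinaryOutcomeData(s=6, f=4))
        sol = optimize_stacking_weights(table)
        assert sol.flat_optimum
        # the combined predictive is identified even though weights are not
        assert combined_loo_density(sol.weights, table, 1) == pytest.approx(
            table.q1[0], abs=1e-10
        )

    def test_sharp_optimum_not_flagged_flat(self, three_interval_table):
        assert not optimize_stacking_weights(three_interval_table).flat_optimum

    def test_undefined_models_excluded_with_zero_weight(self):
        ms = ModelSet([PointMassModel(1.0), BetaIntervalModel(1, 1)], prior_probs=[0.5, 0.5])
        with pytest.warns(UserWarning):
            table = loo_predictive_table(ms, BinaryOutcomeData(s=9, f=1))
        sol = optimize_stacking_weights(table)
        assert sol.weights[0] == 0.0
        assert sol.weights[1] == pytest.approx(1.0)

    def test_no_feasible_model_raises(self):
        with pytest.warns(UserWarning):
            table = loo_predictive_table(
                [PointMassModel(1.0)], BinaryOutcomeData(s=9, f=1)
            )
        with pytest.raises(ZeroProbabilityError):
            optimize_stacking_weights(table)


class TestStackingSummaries:
    def test_three_interval_predictive_is_half(
        self, three_interval_set, three_interval_table, balanced_data
    ):
        sol = optimize_stacking_weights(three_interval_table)
        got = stacking_predictive(sol, three_interval_set, balanced_data)
        assert got == pytest.approx(0.5, abs=1e-10)

    def test_general_law_predicts_certain_success(self):
        ms = ModelSet(
            [PointMassModel(1.0), BetaIntervalModel(1, 1)], prior_probs=[0.5, 0.5]
        )
        data = BinaryOutcomeData(s=5, f=0)
        sol = optimize_stacking_weights(loo_predictive_table(ms, data))
        assert stacking_predictive(sol, ms, data) == pytest.approx(1.0, abs=1e-3)

    def test_density_zero_at_half_when_weight_splits_outer_models(
        self, three_interval_set, three_interval_table, balanced_data
    ):
        """theta = .5 lies outside both supported intervals, so the stacking
        posterior mixture has density 0 there."""
        sol = optimize_stacking_weights(three_interval_table)
        dens = stacking_posterior_density(
            sol, three_interval_set, balanced_data, np.array([0.5])
        )
        assert dens[0] == 0.0

    def test_density_integrates_to_one(
        self, three_interval_set, three_interval_table, balanced_data
    ):
        sol = optimize_stacking_weights(three_interval_table)
        grid = np.linspace(0, 1, 200001)
        dens = stacking_posterior_density(sol, three_interval_set, balanced_data, grid)
        assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-4)

    def test_unit_weight_reproduces_single_truncated_posterior(
        self, three_interval_set, three_interval_table, balanced_data
    ):
        from bernstack import StackingSolution, posterior_density

        sol = StackingSolution(
            weights=np.array([0.0, 1.0, 0.0]),
            objective_value=0.0,
            converged=True,
            flat_optimum=False,
        )
        grid = np.linspace(0, 1, 101)
        dens = stacking_posterior_density(sol, three_interval_set, balanced_data, grid)
        expected = posterior_density(three_interval_set.models[1], balanced_data, grid)
        assert dens == pytest.approx(expected, abs=1e-12)
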