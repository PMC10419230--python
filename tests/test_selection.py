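"""GA / SA / ACO / CARS selectors: oracles, schedules and determinism."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest

import spoilwarn as sw
from spoilwarn.selection import _aco_inclusion_probability

from conftest import make_toy

CV3 = sw.CVConfig(n_folds=3, shuffle_seed=0, max_components=3)


def exhaustive_best_rmsecv(X, y, cv, subset_size=None):
    """Brute-force oracle: best RMSECV over all variable subsets
    (optionally restricted to a fixed subset size)."""
    p = X.shape[1]
    best = (math.inf, None)
    if subset_size is None:
        candidates = itertools.chain.from_iterable(
            itertools.combinations(range(1, p + 1), k) for k in range(1, p + 1)
        )
    else:
        candidates = itertools.combinations(range(1, p + 1), subset_size)
    for subset in candidates:
        value = sw.fitness(X, y, np.array(subset), cv)
        if value < best[0]:
            best = (value, subset)
    return best


class TestFitness:
    def test_informative_subset_beats_random_noise_subset(
        self, toy_single_informative
    ):
        X, y = toy_single_informative
        informative = sw.fitness(X, y, np.array([4]), CV3)
        noise = sw.fitness(X, y, np.array([1, 7, 9]), CV3)
        assert informative < noise

    def test_deterministic_given_seed(self, toy_single_informative):
        X, y = toy_single_informative
        subset = np.array([2, 4, 6])
        assert sw.fitness(X, y, subset, CV3) == sw.fitness(X, y, subset, CV3)

    def test_empty_subset_rejected(self, toy_single_informative):
        X, y = toy_single_informative
        with pytest.raises(ValueError, match="non-empty"):
            sw.fitness(X, y, np.array([], dtype=int), CV3)


class TestGA:
    def test_recovers_single_informative_variable(self, toy_single_informative):
        X, y = toy_single_informative
        config = sw.GAConfig(
            population_size=20, max_iterations=25,
            init_inclusion_probability=0.3, seed=0,
        )
        result = sw.select_ga(X, y, config, CV3)
        assert 4 in result.selected_indices
        # the oracle's best subset also contains the informative variable
        _, oracle_subset = exhaustive_best_rmsecv(X, y, CV3)
        assert 4 in oracle_subset

    def test_same_seed_identical_result(self, toy_single_informative):
        X, y = toy_single_informative
        config = sw.GAConfig(population_size=12, max_iterations=5, seed=3)
        a = sw.select_ga(X, y, config, CV3)
        b = sw.select_ga(X, y, config, CV3)
        assert np.array_equal(a.selected_indices, b.selected_indices)
        assert a.rmsecv_trace == b.rmsecv_trace

    def test_trace_covers_every_generation(self, toy_single_informative):
        X, y = toy_single_informative
        config = sw.GAConfig(population_size=12, max_iterations=10, seed=1)
        trace = sw.select_ga(X, y, config, CV3).rmsecv_trace
        assert len(trace) == config.max_iterations + 1
        assert all(np.isfinite(trace))

    def test_config_validation(self):
        with pytest.raises(ValueError, match="population_size"):
            sw.GAConfig(population_size=5, deletion_group=5)
        with pytest.raises(ValueError, match="mutation_rate"):
            sw.GAConfig(mutation_rate=1.5)


class TestSA:
    def test_metropolis_always_accepts_improvements(self):
        rng = np.random.default_rng(0)
        assert all(
            sw.metropolis_accept(-0.5, t, rng) for t in (10.0, 1.0, 1e-9)
        )

    def test_metropolis_acceptance_frequency_matches_boltzmann(self):
        delta_e, temperature = 0.8, 2.0
        expected = math.exp(-delta_e / temperature)
        rng = np.random.default_rng(123)
        n = 10_000
        accepted = sum(
            sw.metropolis_accept(delta_e, temperature, rng) for _ in range(n)
        )
        se = math.sqrt(expected * (1 - expected) / n)
        assert abs(accepted / n - expected) < 3 * se

    def test_no_worsening_moves_accepted_in_cold_limit(self):
        rng = np.random.default_rng(5)
        assert not any(
            sw.metropolis_accept(0.5, 1e-12, rng) for _ in range(1000)
        )

    def test_best_state_no_worse_than_any_initial_window(
        self, toy_single_informative
    ):
        X, y = toy_single_informative
        config = sw.SAConfig(
            window_start_width=2, window_end_width=3,
            markov_chain_length=4, cooling_coefficient=0.7, seed=0,
        )
        result = sw.select_sa(X, y, config, CV3)
        best = sw.fitness(X, y, result.selected_indices, CV3)
        assert best <= result.rmsecv_trace[0] + 1e-12
        assert all(
            b <= a + 1e-12
            for a, b in zip(result.rmsecv_trace, result.rmsecv_trace[1:])
        )

    def test_recovers_two_informative_variables_on_p12_toy(self):
        X, y = make_toy(n=36, p=12, informative=(3, 9), noise_sd=0.1, seed=2)
        # single-variable moves: with width-2 states a 2-point exchange
        # would replace the whole subset and degenerate to random search
        config = sw.SAConfig(
            window_start_width=2, window_end_width=2,
            markov_chain_length=8, cooling_coefficient=0.85,
            swap_count_per_step=1, seed=1,
        )
        result = sw.select_sa(X, y, config, CV3)
        oracle_value, oracle_subset = exhaustive_best_rmsecv(
            X, y, CV3, subset_size=2
        )
        assert set(oracle_subset) == {3, 9}
        assert set(result.selected_indices) == {3, 9}

    def test_window_wider_than_feature_count_rejected(self):
        X, y = make_toy(n=20, p=5, seed=0)
        config = sw.SAConfig(window_start_width=6, window_end_width=6)
        with pytest.raises(ValueError, match="window width"):
            sw.select_sa(X, y, config, CV3)

    def test_same_seed_identical_result(self, toy_single_informative):
        X, y = toy_single_informative
        config = sw.SAConfig(
            window_start_width=2, window_end_width=3,
            markov_chain_length=3, cooling_coefficient=0.7, seed=8,
        )
        a = sw.select_sa(X, y, config, CV3)
        b = sw.select_sa(X, y, config, CV3)
        assert np.array_equal(a.selected_indices, b.selected_indices)


class TestACO:
    def _config(self, seed=0):
        return sw.ACOConfig(
            population_size=15, max_cycles=2, max_iterations=8,
            target_subset_size=3, seed=seed,
        )

    def test_pheromone_mass_concentrates_on_informative_variable(
        self, toy_single_informative
    ):
        X, y = toy_single_informative
        result = sw.select_aco(X, y, self._config(), CV3)
        scores = result.variable_scores
        assert scores[3] == scores.max()  # variable 4, 0-based position 3
        assert 4 in result.selected_indices

    def test_scores_remain_finite_probabilities(self, toy_single_informative):
        X, y = toy_single_informative
        result = sw.select_aco(X, y, self._config(seed=2), CV3)
        assert np.isfinite(result.variable_scores).all()
        assert (result.variable_scores >= 0).all()
        assert (result.variable_scores <= 1).all()

    def test_same_seed_identical_result(self, toy_single_informative):
        X, y = toy_single_informative
        a = sw.select_aco(X, y, self._config(seed=5), CV3)
        b = sw.select_aco(X, y, self._config(seed=5), CV3)
        assert np.array_equal(a.selected_indices, b.selected_indices)

    def test_uniform_pheromone_matches_target_subset_size(self):
        prob = _aco_inclusion_probability(np.ones(50), target_size=10)
        np.testing.assert_allclose(prob, 0.2)


class TestCARS:
    def test_retention_schedule_boundary_conditions(self):
        for p, n_runs in [(30, 10), (3000, 50), (100, 25)]:
            r = sw.cars_retention_schedule(p, n_runs)
            assert r[0] == pytest.approx(1.0)
            assert r[-1] * p == pytest.approx(2.0)
            assert (np.diff(r) < 0).all()

    def test_live_set_sizes_non_increasing(self, toy_single_informative):
        X, y = toy_single_informative
        config = sw.CARSConfig(n_monte_carlo_runs=8, max_components=3, seed=0)
        result = sw.select_cars(X, y, config, CV3)
        sizes = result.sizes_before_resampling
        assert all(b <= a for a, b in zip(sizes, sizes[1:]))
        assert sizes[-1] == 2

    def test_informative_variable_survives_the_schedule(
        self, toy_single_informative
    ):
        X, y = toy_single_informative
        config = sw.CARSConfig(n_monte_carlo_runs=8, max_components=3, seed=1)
        result = sw.select_cars(X, y, config, CV3)
        assert 4 in result.selected_indices

    def test_same_seed_identical_result(self, toy_single_informative):
        X, y = toy_single_informative
        config = sw.CARSConfig(n_monte_carlo_runs=6, max_components=3, seed=4)
        a = sw.select_cars(X, y, config, CV3)
        b = sw.select_cars(X, y, config, CV3)
        assert np.array_equal(a.selected_indices, b.selected_indices)
        assert a.rmsecv_trace == b.rmsecv_trace


class TestOracleEquivalence:
    """GA and SA reach near-exhaustive-best RMSECV in >= 4 of 5 seeds."""

    def test_ga_within_five_percent_of_exhaustive_best(self):
        hits = 0
        for seed in range(5):
            X, y = make_toy(
                n=30, p=8, informative=(2, 6), noise_sd=0.15, seed=seed
            )
            oracle_value, _ = exhaustive_best_rmsecv(X, y, CV3)
            config = sw.GAConfig(
                population_size=20, max_iterations=30,
                init_inclusion_probability=0.3, seed=seed,
            )
            result = sw.select_ga(X, y, config, CV3)
            hits += min(result.rmsecv_trace) <= oracle_value * 1.05
        assert hits >= 4

    def test_sa_within_five_percent_of_exhaustive_best(self):
        hits = 0
        for seed in range(5):
            X, y = make_toy(
                n=30, p=10, informative=(3, 8), noise_sd=0.15, seed=seed
            )
            oracle_value, _ = exhaustive_best_rmsecv(X, y, CV3, subset_size=2)
            config = sw.SAConfig(
                window_start_width=2, window_end_width=2,
                markov_chain_length=8, cooling_coefficient=0.85,
                swap_count_per_step=1, seed=seed,
            )
            result = sw.select_sa(X, y, config, CV3)
            achieved = sw.fitness(X, y, result.selected_indices, CV3)
            hits += achieved <= oracle_value * 1.05
        assert hits >= 4


class TestRunAll:
    def test_four_results_with_valid_indices(self, toy_single_informative):
        X, y = toy_single_informative
        configs = {
            "GA": sw.GAConfig(population_size=10, max_iterations=5, seed=0,
                              init_inclusion_probability=0.3),
            "SA": sw.SAConfig(window_start_width=2, window_end_width=2,
                              markov_chain_length=3, cooling_coefficient=0.7,
                              seed=0),
            "ACO": sw.ACOConfig(population_size=10, max_cycles=1,
                                max_iterations=5, target_subset_size=3, seed=0),
            "CARS": sw.CARSConfig(n_monte_carlo_runs=5, max_components=3,
                                  seed=0),
        }
        results = sw.run_all_selectors(X, y, configs, CV3)
        assert set(results) == {"GA", "SA", "ACO", "CARS"}
        for result in results.values():
            assert result.selected_indices.size > 0
            assert result.selected_indices.min() >= 1
            assert result.selected_indices.max() <= X.shape[1]

    def test_one_failure_does_not_abort_the_others(self, toy_single_informative):
        X, y = toy_single_informative
        configs = {
            "SA": sw.SAConfig(window_start_width=99, window_end_width=99),
            "CARS": sw.CARSConfig(n_monte_carlo_runs=5, max_components=3,
                                  seed=0),
        }
        with pytest.warns(UserWarning, match="SA selection failed"):
            results = sw.run_all_selectors(X, y, configs, CV3)
        assert "CARS" in results and "SA" not in results

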