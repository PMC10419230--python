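"""Wrapper variable selection around PLS: GA, SA, ACO and CARS.

All four algorithms share the same fitness — k-fold RMSECV of a PLS model
restricted to a candidate variable subset (lower is fitter) — and return
a :class:`SelectionResult` carrying the chosen 1-based variable numbers,
the fitness trace and per-variable final scores.

Default parameters are the settings used in the reference study:

* GA — 30 chromosomes, deletion group 5, mutation rate 0.01, crossover
  probability 0.5, 100 generations.
* SA — initial temperature 10, end temperature 1, Markov chain length 10,
  cooling coefficient 0.95, window widths 10..20 (step 1), 2 points
  exchanged per move, at most 12 PLS components.
* ACO — 50 ants, 10 cycles of 50 iterations, selection probability
  threshold P = 0.3, significance factor Q = 0.01.
* CARS — at most 15 components, 5 CV folds, 2000 Monte-Carlo runs.

Where the study leaves an algorithmic detail open (GA parent selection,
ACO pheromone update, CARS calibration fraction), the choices made here
are documented in the project's methods note.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .chemometrics import CVConfig, fit_pls, kfold_rmsecv


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 30
    deletion_group: int = 5
    mutation_rate: float = 0.01
    crossover_probability: float = 0.5
    max_iterations: int = 100
    frequency_threshold: float = 0.5
    init_inclusion_probability: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("mutation_rate", "crossover_probability",
                     "frequency_threshold", "init_inclusion_probability"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.population_size <= self.deletion_group:
            raise ValueError("population_size must exceed deletion_group")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be positive")


@dataclass(frozen=True)
class SAConfig:
    initial_temperature: float = 10.0
    end_temperature: float = 1.0
    markov_chain_length: int = 10
    cooling_coefficient: float = 0.95
    window_start_width: int = 10
    window_end_width: int = 20
    window_step: int = 1
    swap_count_per_step: int = 2
    max_components: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.cooling_coefficient < 1.0:
            raise ValueError("cooling_coefficient must lie in (0, 1)")
        if not 0.0 < self.end_temperature < self.initial_temperature:
            raise ValueError("need 0 < end_temperature < initial_temperature")
        if self.window_start_width < 1 or self.window_end_width < self.window_start_width:
            raise ValueError("window widths must be positive with start <= end")
        if self.markov_chain_length < 1 or self.swap_count_per_step < 1:
            raise ValueError("chain length and swap count must be positive")


@dataclass(frozen=True)
class ACOConfig:
    population_size: int = 50
    max_cycles: int = 10
    max_iterations: int = 50
    selection_probability_threshold: float = 0.3
    significance_factor: float = 0.01
    evaporation_rate: float = 0.1
    target_subset_size: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.selection_probability_threshold < 1.0:
            raise ValueError("selection_probability_threshold must lie in (0, 1)")
        if self.significance_factor <= 0:
            raise ValueError("significance_factor must be positive")
        if not 0.0 < self.evaporation_rate < 1.0:
            raise ValueError("evaporation_rate must lie in (0, 1)")
        if min(self.population_size, self.max_cycles, self.max_iterations,
               self.target_subset_size) < 1:
            raise ValueError("counts must be positive")


@dataclass(frozen=True)
class CARSConfig:
    max_components: int = 15
    n_folds: int = 5
    n_monte_carlo_runs: int = 2000
    calibration_fraction_per_run: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_monte_carlo_runs < 2:
            raise ValueError("n_monte_carlo_runs must be at least 2")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if not 0.0 < self.calibration_fraction_per_run <= 1.0:
            raise ValueError("calibration_fraction_per_run must lie in (0, 1]")
        if self.max_components < 1:
            raise ValueError("max_components must be positive")


@dataclass
class SelectionResult:
    """Outcome of one selection run (1-based variable numbers)."""

    algorithm: str
    selected_indices: np.ndarray
    rmsecv_trace: list[float]
    variable_scores: np.ndarray
    config: object
    seed: int
    n_features: int

    def __post_init__(self) -> None:
        self.selected_indices = np.unique(
            np.asarray(self.selected_indices, dtype=int)
        )
        if self.selected_indices.size == 0:
            raise ValueError("selection must be non-empty")
        if (self.selected_indices.min() < 1
                or self.selected_indices.max() > self.n_features):
            raise ValueError("selected index outside 1..n_features")


def fitness(
    features: np.ndarray,
    labels: np.ndarray,
    subset: np.ndarray,
    cv: CVConfig,
) -> float:
    """Selector fitness: minimum k-fold RMSECV over component counts."""
    return kfold_rmsecv(features, labels, subset, cv).best_rmsecv


class _CachedFitness:
    """Memoized fitness shared within one selector run."""

    def __init__(self, features: np.ndarray, labels: np.ndarray, cv: CVConfig):
        self.features = features
        self.labels = labels
        self.cv = cv
        self._cache: dict[frozenset[int], float] = {}
        self.n_evaluations = 0

    def __call__(self, subset) -> float:
        key = frozenset(int(i) for i in subset)
        if key not in self._cache:
            self.n_evaluations += 1
            self._cache[key] = fitness(
                self.features, self.labels, np.asarray(sorted(key)), self.cv
            )
        return self._cache[key]


# ---------------------------------------------------------------- genetic

def _repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if not mask.any():
        mask = mask.copy()
        mask[rng.integers(mask.size)] = True
    return mask


def select_ga(
    features: np.ndarray,
    labels: np.ndarray,
    config: GAConfig,
    cv: CVConfig,
) -> SelectionResult:
    """Genetic algorithm over binary variable masks.

    Steady-state generational scheme: each generation breeds
    ``deletion_group`` offspring (tournament-of-2 parents, uniform
    crossover, bitwise mutation) which replace the worst chromosomes; the
    elite remainder survives unchanged.  After the final generation,
    variables whose selection frequency across the population reaches
    ``frequency_threshold`` are returned (the fittest chromosome's
    variables if none do).
    """
    rng = np.random.default_rng(config.seed)
    p = np.asarray(features).shape[1]
    fit = _CachedFitness(np.asarray(features, float), np.asarray(labels, float), cv)

    pop = rng.random((config.population_size, p)) < config.init_inclusion_probability
    pop = np.vstack([_repair(row, rng) for row in pop])
    energy = np.array([fit(np.flatnonzero(row) + 1) for row in pop])

    trace = [float(energy.min())]
    for _ in range(config.max_iterations):
        children = []
        for _ in range(config.deletion_group):
            contenders = rng.integers(config.population_size, size=(2, 2))
            pa = pop[contenders[0][np.argmin(energy[contenders[0]])]]
            pb = pop[contenders[1][np.argmin(energy[contenders[1]])]]
            if rng.random() < config.crossover_probability:
                take_b = rng.random(p) < 0.5
                child = np.where(take_b, pb, pa)
            else:
                child = pa.copy()
            flip = rng.random(p) < config.mutation_rate
            child = _repair(child ^ flip, rng)
            children.append(child)
        worst = np.argsort(energy)[-config.deletion_group:]
        for slot, child in zip(worst, children):
            pop[slot] = child
            energy[slot] = fit(np.flatnonzero(child) + 1)
        trace.append(float(energy.min()))

    freq = pop.mean(axis=0)
    selected = np.flatnonzero(freq >= config.frequency_threshold) + 1
    if selected.size == 0:
        selected = np.flatnonzero(pop[np.argmin(energy)]) + 1
    return SelectionResult(
        algorithm="GA",
        selected_indices=selected,
        rmsecv_trace=trace,
        variable_scores=freq,
        config=config,
        seed=config.seed,
        n_features=p,
    )


# ------------------------------------------------------------- annealing

def metropolis_accept(
    delta_e: float, temperature: float, rng: np.random.Generator
) -> bool:
    """Metropolis criterion: always accept improvements, accept a
    worsening move with probability exp(-delta_e / T)."""
    if delta_e <= 0:
        return True
    if temperature <= 0:
        return False
    return bool(rng.random() < math.exp(-delta_e / temperature))


def select_sa(
    features: np.ndarray,
    labels: np.ndarray,
    config: SAConfig,
    cv: CVConfig,
) -> SelectionResult:
    """Simulated annealing over fixed-size variable subsets.

    For each window width from ``window_start_width`` to
    ``window_end_width`` (step ``window_step``) one annealing pass runs:
    the state starts as a contiguous index window of that width placed at
    random, and each move exchanges ``swap_count_per_step`` selected
    variables for unselected ones.  Moves follow the Metropolis
    criterion under geometric cooling.  The best state ever visited
    across all passes is returned.
    """
    rng = np.random.default_rng(config.seed)
    X = np.asarray(features, float)
    y = np.asarray(labels, float)
    p = X.shape[1]
    cv_eff = replace(cv, max_components=min(cv.max_components, config.max_components))
    fit = _CachedFitness(X, y, cv_eff)

    best_state: np.ndarray | None = None
    best_energy = math.inf
    trace: list[float] = []
    for width in range(config.window_start_width, config.window_end_width + 1,
                       config.window_step):
        if width > p:
            raise ValueError(f"window width {width} exceeds {p} variables")
        start = int(rng.integers(p - width + 1))
        state = np.zeros(p, dtype=bool)
        state[start:start + width] = True
        energy = fit(np.flatnonzero(state) + 1)
        if energy < best_energy:
            best_energy, best_state = energy, state.copy()
        temperature = config.initial_temperature
        while temperature > config.end_temperature:
            for _ in range(config.markov_chain_length):
                inside = np.flatnonzero(state)
                outside = np.flatnonzero(~state)
                n_swap = min(config.swap_count_per_step, inside.size, outside.size)
                if n_swap == 0:
                    break
                out_pick = rng.choice(inside, size=n_swap, replace=False)
                in_pick = rng.choice(outside, size=n_swap, replace=False)
                proposal = state.copy()
                proposal[out_pick] = False
                proposal[in_pick] = True
                new_energy = fit(np.flatnonzero(proposal) + 1)
                if metropolis_accept(new_energy - energy, temperature, rng):
                    state, energy = proposal, new_energy
                    if energy < best_energy:
                        best_energy, best_state = energy, state.copy()
            temperature *= config.cooling_coefficient
        trace.append(float(best_energy))

    assert best_state is not None
    scores = np.zeros(p)
    scores[best_state] = 1.0
    return SelectionResult(
        algorithm="SA",
        selected_indices=np.flatnonzero(best_state) + 1,
        rmsecv_trace=trace,
        variable_scores=scores,
        config=config,
        seed=config.seed,
        n_features=p,
    )


# ------------------------------------------------------------ ant colony

def _aco_inclusion_probability(pheromone: np.ndarray, target_size: int) -> np.ndarray:
    """Normalized per-variable inclusion probability.

    Pheromone shares are rescaled so that a uniform trail yields an
    expected subset size of ``target_size``, then clipped to [0, 1]; as
    pheromone concentrates, favoured variables saturate toward 1.
    """
    share = pheromone / pheromone.sum()
    return np.clip(share * target_size, 0.0, 1.0)


def select_aco(
    features: np.ndarray,
    labels: np.ndarray,
    config: ACOConfig,
    cv: CVConfig,
) -> SelectionResult:
    """Ant colony optimization over variable subsets.

    Each iteration every ant samples a subset by Bernoulli draws with the
    pheromone-derived inclusion probabilities; pheromone evaporates at
    ``evaporation_rate`` and each ant deposits Q / RMSECV on its
    variables.  Cycles restart the iteration loop while keeping the
    pheromone trail.  Variables whose final inclusion probability reaches
    the threshold P are returned; if none do, the top-k by pheromone are
    returned with a warning (k = the mean ant subset size).
    """
    rng = np.random.default_rng(config.seed)
    X = np.asarray(features, float)
    y = np.asarray(labels, float)
    p = X.shape[1]
    fit = _CachedFitness(X, y, cv)

    pheromone = np.ones(p)
    trace: list[float] = []
    last_sizes: list[int] = []
    for _cycle in range(config.max_cycles):
        for _iteration in range(config.max_iterations):
            prob = _aco_inclusion_probability(pheromone, config.target_subset_size)
            deposits = np.zeros(p)
            best_iter = math.inf
            last_sizes = []
            for _ant in range(config.population_size):
                mask = rng.random(p) < prob
                if not mask.any():
                    mask[rng.choice(p, p=pheromone / pheromone.sum())] = True
                subset = np.flatnonzero(mask) + 1
                last_sizes.append(subset.size)
                e = fit(subset)
                best_iter = min(best_iter, e)
                deposits[mask] += config.significance_factor / max(e, 1e-12)
            pheromone = (1.0 - config.evaporation_rate) * pheromone + deposits
            trace.append(float(best_iter))

    prob = _aco_inclusion_probability(pheromone, config.target_subset_size)
    selected = np.flatnonzero(prob >= config.selection_probability_threshold) + 1
    if selected.size == 0:
        k = max(1, int(round(float(np.mean(last_sizes)))))
        selected = np.sort(np.argsort(pheromone)[-k:]) + 1
        warnings.warn(
            "no variable reached the selection probability threshold "
            f"P={config.selection_probability_threshold}; returning the top "
            f"{k} variables by pheromone",
            stacklevel=2,
        )
    return SelectionResult(
        algorithm="ACO",
        selected_indices=selected,
        rmsecv_trace=trace,
        variable_scores=prob,
        config=config,
        seed=config.seed,
        n_features=p,
    )


# ------------------------------------------------------------------ CARS

def cars_retention_schedule(n_features: int, n_runs: int) -> np.ndarray:
    """Exponential-decay retention ratio r_i for runs i = 1..N.

    Boundary conditions: r_1 = 1 (all variables live) and
    r_N = 2 / p (exactly two variables at the last run), giving
    a = (p/2)^(1/(N-1)) and k = ln(p/2) / (N-1) in r_i = a exp(-k i).
    """
    p = n_features
    n = n_runs
    if p < 2:
        raise ValueError("need at least 2 variables")
    a = (p / 2.0) ** (1.0 / (n - 1))
    k = math.log(p / 2.0) / (n - 1)
    i = np.arange(1, n + 1)
    return a * np.exp(-k * i)


def select_cars(
    features: np.ndarray,
    labels: np.ndarray,
    config: CARSConfig,
    cv: CVConfig | None = None,
) -> SelectionResult:
    """Competitive adaptive reweighted sampling.

    Each Monte-Carlo run fits PLS (component count by RMSECV, capped at
    ``max_components``) on a random calibration subsample restricted to
    the live variables, forcibly keeps the ceil(r_i * p) variables of
    largest absolute autoscaled coefficient, then resamples the live set
    by coefficient-weighted sampling (ARS).  Each run's live set is
    scored by full-sample RMSECV; the best-scoring set is returned.
    """
    rng = np.random.default_rng(config.seed)
    X = np.asarray(features, float)
    y = np.asarray(labels, float)
    n, p = X.shape
    cv_record = CVConfig(
        n_folds=config.n_folds,
        shuffle_seed=config.seed if cv is None else cv.shuffle_seed,
        max_components=config.max_components,
    )
    schedule = cars_retention_schedule(p, config.n_monte_carlo_runs)

    live = np.arange(1, p + 1)
    best_set: np.ndarray | None = None
    best_rmsecv = math.inf
    trace: list[float] = []
    sizes_before_resampling: list[int] = []
    for r_i in schedule:
        n_cal = max(2, int(round(config.calibration_fraction_per_run * n)))
        cal = rng.choice(n, size=min(n_cal, n), replace=False)
        inner = kfold_rmsecv(X[cal], y[cal], live, cv_record)
        model = fit_pls(
            X[cal], y[cal], inner.best_n_components, feature_indices=live
        )
        weight = np.abs(model.coefficients * model.scale_factors)
        # tolerance guards the analytic boundary r_N * p = 2 against FP noise
        n_keep = min(live.size, max(2, math.ceil(r_i * p - 1e-9)))
        sizes_before_resampling.append(n_keep)
        order = np.argsort(weight)[::-1]
        kept = live[order[:n_keep]]
        kept_w = weight[order[:n_keep]]
        if kept_w.sum() <= 0:
            kept_w = np.ones_like(kept_w)
        draws = rng.choice(kept, size=n_keep, replace=True, p=kept_w / kept_w.sum())
        new_live = np.unique(draws)
        if new_live.size < 2:
            new_live = np.sort(kept[np.argsort(kept_w)[::-1][:2]])
        live = new_live
        run_rmsecv = kfold_rmsecv(X, y, live, cv_record).best_rmsecv
        trace.append(float(run_rmsecv))
        if run_rmsecv < best_rmsecv:
            best_rmsecv = run_rmsecv
            best_set = live.copy()
        if live.size < 2:
            break

    assert best_set is not None
    scores = np.zeros(p)
    scores[best_set - 1] = 1.0
    result = SelectionResult(
        algorithm="CARS",
        selected_indices=best_set,
        rmsecv_trace=trace,
        variable_scores=scores,
        config=config,
        seed=config.seed,
        n_features=p,
    )
    result.sizes_before_resampling = sizes_before_resampling  # type: ignore[attr-defined]
    return result


# ------------------------------------------------------------ orchestration

_SELECTORS: dict[str, Callable] = {
    "GA": select_ga,
    "SA": select_sa,
    "ACO": select_aco,
    "CARS": select_cars,
}


def run_all_selectors(
    features: np.ndarray,
    labels: np.ndarray,
    configs: dict[str, object],
    cv: CVConfig,
) -> dict[str, SelectionResult]:
    """Run GA, SA, ACO and CARS with a shared CV; per-algorithm failures
    are reported as warnings without aborting the others."""
    results: dict[str, SelectionResult] = {}
    for name, selector in _SELECTORS.items():
        config = configs.get(name)
        if config is None:
            continue
        try:
            results[name] = selector(features, labels, config, cv)
        except Exception as exc:  # noqa: BLE001 - isolate per-algorithm failure
            warnings.warn(f"{name} selection failed: {exc}", stacklevel=2)
    if not results:
        raise RuntimeError("every selection algorithm failed")
    return results


def default_selector_configs(seed: int = 0) -> dict[str, object]:
    """The four selector configurations at their reference settings."""
    return {
        "GA": GAConfig(seed=seed),
        "SA": SAConfig(seed=seed),
        "ACO": ACOConfig(seed=seed),
        "CARS": CARSConfig(seed=seed),
    }


def test_scale_selector_configs(seed: int = 0) -> dict[str, object]:
    """Reduced-budget selector settings for desk-scale experiments.

    Same algorithms and data conditions, smaller search budgets: GA 15
    generations, SA windows 10..12 with faster cooling, ACO 2x10
    iterations with 20 ants, CARS 50 Monte-Carlo runs.
    """
    return {
        "GA": GAConfig(max_iterations=15, population_size=20,
                       init_inclusion_probability=0.05, seed=seed),
        "SA": SAConfig(window_start_width=10, window_end_width=12,
                       cooling_coefficient=0.85, markov_chain_length=5,
                       seed=seed),
        "ACO": ACOConfig(population_size=20, max_cycles=2, max_iterations=10,
                         seed=seed),
        "CARS": CARSConfig(n_monte_carlo_runs=50, seed=seed),
    }
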