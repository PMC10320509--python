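"""Differential evolution with fitness-proportional parent sampling.

Standard DE over a population of ``n_pop`` candidate weight vectors of
dimension M.  Donor parents for the mutation

    trial = X^{r1} + F * (X^{r2} - X^{r3})

are drawn without replacement, preferentially from fitter members: with
normalized fitness f~ = F_fit / max_j F_fit in (0, 1], member r is sampled
with probability proportional to exp(-f~_r / max_j(1 - f~_j)).  Crossover is
per-component binomial with one forced component by default (the literal
per-member variant is available as a config mode).  Selection is strictly
elitist per slot: the mutant replaces the current member only if its fitness
is strictly lower.  The run terminates when the mean absolute change of the
best fitness over the last ``termination_window`` generations falls below
``termination_threshold``, or at ``max_generations``.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Probabilities below which the selection-probability denominator counts as degenerate
#: (all fitness values equal) and selection falls back to uniform.
_EQUAL_FITNESS_EPS = 1e-12


@dataclass
class DEConfig:
    """Differential-evolution hyperparameters."""

    n_pop: int = 50                 # population size (candidate weight vectors)
    mutation_factor: float = 0.5    # F
    crossover_rate: float = 0.9     # CR
    crossover_mode: str = "per_component"   # or "per_member"
    init_half_range: float = 1.0    # init ~ U(-h, +h) per component
    termination_window: int = 20    # generations averaged for termination
    termination_threshold: float = 1e-3   # mean |change in best fitness|
    max_generations: int = 2000
    seed: int = 0
    vectorized_fitness: bool = False  # fitness_fn accepts an (N, M) batch

    def __post_init__(self):
        if self.n_pop < 4:
            raise ValueError("n_pop must be >= 4 (three donors + target)")
        if not 0 <= self.crossover_rate <= 1:
            raise ValueError("crossover_rate must lie in [0, 1]")
        if self.crossover_mode not in ("per_component", "per_member"):
            raise ValueError("crossover_mode must be per_component or per_member")
        if self.termination_window < 1 or self.termination_threshold < 0:
            raise ValueError("invalid termination settings")


@dataclass
class DEState:
    """Population snapshot: member vectors, their fitness, generation count."""

    population: np.ndarray          # (n_pop, M)
    fitness: np.ndarray             # (n_pop,)
    generation: int = 0

    @property
    def best_index(self) -> int:
        return int(np.argmin(self.fitness))

    @property
    def best_fitness(self) -> float:
        return float(self.fitness[self.best_index])


@dataclass
class DEResult:
    """Best member of the final generation plus the convergence history."""

    weights: np.ndarray
    fitness: float
    converged: bool
    n_generations: int
    history: pd.DataFrame = field(repr=False)   # generation, best_fitness, mean_fitness


def _evaluate(fitness_fn, population: np.ndarray, vectorized: bool) -> np.ndarray:
    if vectorized:
        out = np.asarray(fitness_fn(population), float)
        if out.shape != (population.shape[0],):
            raise ValueError("vectorized fitness_fn must map (N, M) to (N,)")
        return out
    return np.array([float(fitness_fn(m)) for m in population])


def initialize(fitness_fn, dimension: int, config: DEConfig,
               rng: np.random.Generator | None = None) -> DEState:
    """Uniform zero-mean initial population with evaluated fitness."""
    if dimension < 1:
        raise ValueError("dimension must be >= 1")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    h = config.init_half_range
    pop = rng.uniform(-h, h, size=(config.n_pop, dimension))
    fit = _evaluate(fitness_fn, pop, config.vectorized_fitness)
    return DEState(population=pop, fitness=fit, generation=0)


def selection_probabilities(fitness: np.ndarray) -> np.ndarray:
    """Fitness-weighted parent-sampling probabilities (lower fitness -> higher p).

    Fitness is normalized to f~ = F / max_j F in (0, 1]; probabilities are
    proportional to exp(-f~ / max_j(1 - f~_j)).  When all fitness values are
    (numerically) equal the denominator vanishes and sampling is uniform.
    Negative fitness values (possible for user-supplied objectives) are
    shifted to positive before the ratio normalization, which leaves the
    ordering intact.
    """
    f = np.asarray(fitness, float)
    if f.size == 0 or not np.all(np.isfinite(f)):
        raise ValueError("fitness values must be finite and non-empty")
    fmin = f.min()
    if fmin <= 0:
        f = f - fmin + 1.0
    f_norm = f / f.max()
    denom = np.max(1.0 - f_norm)
    if denom < _EQUAL_FITNESS_EPS:
        return np.full(f.size, 1.0 / f.size)
    expo = -f_norm / denom
    p = np.exp(expo - expo.max())   # shift: same proportions, no underflow to all-zero
    return p / p.sum()


def _sample_distinct(rng, probabilities: np.ndarray, exclude: int,
                     k: int = 3) -> list[int]:
    """k distinct indices != exclude, drawn by the fitness-weighted probabilities,
    renormalized after each draw."""
    p = probabilities.copy()
    p[exclude] = 0.0
    out = []
    for _ in range(k):
        total = p.sum()
        if total <= 0:    # degenerate leftover mass: fall back to uniform
            avail = [i for i in range(p.size) if i != exclude and i not in out]
            idx = int(rng.choice(avail))
        else:
            idx = int(rng.choice(p.size, p=p / total))
        out.append(idx)
        p[idx] = 0.0
    return out


def mutate(state: DEState, member_index: int, config: DEConfig,
           rng: np.random.Generator,
           probabilities: np.ndarray | None = None) -> np.ndarray:
    """rand/1 donor mutation with fitness-weighted distinct donors."""
    n = state.population.shape[0]
    if n < 4:
        raise ValueError("mutation needs n_pop >= 4")
    if probabilities is None:
        probabilities = selection_probabilities(state.fitness)
    r1, r2, r3 = _sample_distinct(rng, probabilities, member_index)
    X = state.population
    return X[r1] + config.mutation_factor * (X[r2] - X[r3])


def recombine(trial: np.ndarray, current: np.ndarray, config: DEConfig,
              rng: np.random.Generator) -> np.ndarray:
    """Binomial crossover.

    per_component (default): each component takes the trial value with
    probability CR, with one uniformly chosen component always forced from
    the trial.  per_member (literal per-member rule): the whole vector is the trial
    with probability CR, else the current member.
    """
    if config.crossover_mode == "per_member":
        return trial.copy() if rng.random() < config.crossover_rate else current.copy()
    mask = rng.random(trial.size) < config.crossover_rate
    mask[rng.integers(trial.size)] = True
    return np.where(mask, trial, current)


def select(mutant: np.ndarray, current: np.ndarray,
           mutant_fitness: float, current_fitness: float):
    """Greedy selection: the mutant survives only with strictly lower fitness."""
    if mutant_fitness < current_fitness:
        return mutant, mutant_fitness
    return current, current_fitness


def step(state: DEState, fitness_fn, config: DEConfig,
         rng: np.random.Generator) -> DEState:
    """One generation: mutate -> recombine -> select for every member.

    Parent-sampling probabilities are computed once from the entering
    population; mutant fitness is evaluated in one batch.
    """
    probs = selection_probabilities(state.fitness)
    mutants = np.empty_like(state.population)
    for r in range(state.population.shape[0]):
        trial = mutate(state, r, config, rng, probabilities=probs)
        mutants[r] = recombine(trial, state.population[r], config, rng)
    mfit = _evaluate(fitness_fn, mutants, config.vectorized_fitness)
    better = mfit < state.fitness
    new_pop = np.where(better[:, None], mutants, state.population)
    new_fit = np.where(better, mfit, state.fitness)
    return DEState(population=new_pop, fitness=new_fit,
                   generation=state.generation + 1)


def run(fitness_fn, dimension: int, config: DEConfig | None = None,
        initial_state: DEState | None = None) -> DEResult:
    """Full DE run with windowed best-fitness termination.

    Returns the best member of the last generation; ``converged`` is False
    when ``max_generations`` was exhausted before the termination criterion
    fired.
    """
    config = config or DEConfig()
    rng = np.random.default_rng(config.seed)
    state = initial_state if initial_state is not None else \
        initialize(fitness_fn, dimension, config, rng)
    best_trace = [state.best_fitness]
    rows = [(state.generation, state.best_fitness, float(state.fitness.mean()))]
    converged = False
    while state.generation < config.max_generations:
        state = step(state, fitness_fn, config, rng)
        best_trace.append(state.best_fitness)
        rows.append((state.generation, state.best_fitness,
                     float(state.fitness.mean())))
        w = config.termination_window
        if len(best_trace) > w:
            changes = np.abs(np.diff(best_trace[-(w + 1):]))
            if changes.mean() < config.termination_threshold:
                converged = True
                break
    if not converged:
        logger.warning("DE stopped at max_generations=%d without convergence",
                       config.max_generations)
    history = pd.DataFrame(rows, columns=["generation", "best_fitness",
                                          "mean_fitness"])
    return DEResult(weights=state.population[state.best_index].copy(),
                    fitness=state.best_fitness, converged=converged,
                    n_generations=state.generation, history=history)
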