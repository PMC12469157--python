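"""Blood-sucking leech optimizer (BSLO) and its improved variant (IBSLO).

BSLO is a population metaheuristic modeled on hematophagous leech foraging,
organized as five search strategies: directional exploration (move toward the
incumbent best with randomized step scaling, dominant early), directional
exploitation (contracting local moves around the best, dominant late), a
per-leech directional switching rule with an iteration-dependent threshold,
non-directional search (random relocation of a small subset to keep
diversity), and retracing (re-drawing leeches whose fitness has stagnated).
Moves are clamped to the box bounds and kept only if they do not worsen the
leech (greedy replacement), so the best-so-far trace is monotone.

IBSLO adds two mechanisms on top:

* cubic chaotic-map initialization: positions come from the chaotic recursion
  ``z <- rho * z * (1 - z^2)`` (rho = 2.595 keeps the orbit inside (0, 1)),
  giving a deterministic, well-spread initial population;
* dynamic opposition-based learning (OBL): with some probability per
  iteration, every leech's opposite with respect to the *current population
  extent* is evaluated and the best half of the union survives (elitist
  greedy selection), which accelerates escape from local basins.

Everything minimizes; wrap a maximization objective with a negation.
Objectives receive an (n, dim) position matrix and return n values, so
population evaluation is one vectorized call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = [
    "StrategyParams",
    "OptimizerConfig",
    "Population",
    "OptimizationResult",
    "cubic_map_sequence",
    "initialize_population_chaotic",
    "opposite_point",
    "dynamic_obl_step",
    "bslo_iteration",
    "optimize",
    "as_batch_objective",
]

Objective = Callable[[np.ndarray], np.ndarray]

_CUBIC_RHO = 2.595


@dataclass(frozen=True)
class StrategyParams:
    """BSLO strategy constants.

    switching_power shapes the explore->exploit schedule (the exploration
    probability is ``(1 - t/T)^switching_power``); exploitation_step scales
    the contracting move around the best; nondirectional_fraction is the
    share of the population randomly relocated each iteration; leeches that
    fail to improve for retracing_trigger_count iterations are re-drawn.
    """

    switching_power: float = 1.0
    exploitation_step: float = 1.0
    nondirectional_fraction: float = 0.1
    retracing_trigger_count: int = 15


@dataclass(frozen=True)
class OptimizerConfig:
    dim: int
    bounds: tuple[np.ndarray, np.ndarray] | tuple[float, float]
    population_size: int = 30
    max_iterations: int = 500
    seed: int = 0
    variant: str = "ibslo"
    chaotic_rho: float = _CUBIC_RHO
    obl_probability: float = 0.3
    strategy_params: StrategyParams = field(default_factory=StrategyParams)

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ValueError("population_size must be >= 4")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if not 0.0 <= self.obl_probability <= 1.0:
            raise ValueError("obl_probability must be in [0, 1]")
        if self.variant not in ("bslo", "ibslo"):
            raise ValueError(f"unknown variant {self.variant!r}")
        lo, hi = self.bounds
        lo = np.broadcast_to(np.asarray(lo, dtype=float), (self.dim,)).copy()
        hi = np.broadcast_to(np.asarray(hi, dtype=float), (self.dim,)).copy()
        if not (np.isfinite(lo).all() and np.isfinite(hi).all() and (lo < hi).all()):
            raise ValueError("bounds must be finite with lower < upper")
        object.__setattr__(self, "bounds", (lo, hi))


@dataclass
class Population:
    positions: np.ndarray
    fitness: np.ndarray
    best_position: np.ndarray
    best_fitness: float
    iteration: int = 0
    stagnation: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.stagnation is None:
            self.stagnation = np.zeros(len(self.fitness), dtype=int)

    def _update_best(self) -> None:
        i = int(np.argmin(self.fitness))  # stable: first index on ties
        if self.fitness[i] < self.best_fitness:
            self.best_fitness = float(self.fitness[i])
            self.best_position = self.positions[i].copy()


@dataclass(frozen=True)
class OptimizationResult:
    best_position: np.ndarray
    best_fitness: float
    history: np.ndarray
    evaluations: int


def cubic_map_sequence(z0: float, length: int, rho: float = _CUBIC_RHO) -> np.ndarray:
    """Iterate the cubic chaotic map ``z <- rho * z * (1 - z^2)``.

    For rho in (0, ~2.598] the orbit stays strictly inside (0, 1); the default
    rho = 2.595 is in the chaotic regime.  z0 must avoid the map's fixed
    points (0 and sqrt(1 - 1/rho)) to produce a non-degenerate orbit.
    """
    if not 0.0 < z0 < 1.0:
        raise ValueError(f"z0 must be in (0, 1), got {z0}")
    if length < 1:
        raise ValueError("length must be >= 1")
    out = np.empty(length)
    z = z0
    for k in range(length):
        z = rho * z * (1.0 - z * z)
        out[k] = z
    return out


def initialize_population_chaotic(
    config: OptimizerConfig, objective: Objective
) -> Population:
    """Chaotic-map initial population: one cubic orbit unrolled over all genes."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.bounds
    n, d = config.population_size, config.dim
    z0 = rng.uniform(0.05, 0.95)
    z = cubic_map_sequence(z0, n * d, config.chaotic_rho).reshape(n, d)
    positions = lo + z * (hi - lo)
    fitness = np.asarray(objective(positions), dtype=float)
    i = int(np.argmin(fitness))
    return Population(
        positions=positions, fitness=fitness,
        best_position=positions[i].copy(), best_fitness=float(fitness[i]),
    )


def _initialize_uniform(config: OptimizerConfig, objective: Objective,
                        rng: np.random.Generator) -> Population:
    lo, hi = config.bounds
    positions = rng.uniform(lo, hi, size=(config.population_size, config.dim))
    fitness = np.asarray(objective(positions), dtype=float)
    i = int(np.argmin(fitness))
    return Population(
        positions=positions, fitness=fitness,
        best_position=positions[i].copy(), best_fitness=float(fitness[i]),
    )


def opposite_point(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Opposition-based learning point ``a + b - x`` (elementwise).

    Points outside [a, b] are clamped first, so the result always lies inside
    the interval; the map is an involution on [a, b].
    """
    x = np.clip(np.asarray(x, dtype=float), a, b)
    return a + b - x


def dynamic_obl_step(
    pop: Population, objective: Objective, rng: np.random.Generator,
    obl_probability: float = 0.3,
) -> Population:
    """Dynamic opposition-based learning with elitist union selection.

    With probability ``obl_probability``, oppose every leech against the
    current population's per-dimension min/max (dynamic bounds), evaluate the
    opposites, and keep the best ``population_size`` members of the union.
    Never degrades the best fitness.
    """
    if rng.random() >= obl_probability:
        return pop
    lo = pop.positions.min(axis=0)
    hi = pop.positions.max(axis=0)
    opp = opposite_point(pop.positions, lo, hi)
    opp_fit = np.asarray(objective(opp), dtype=float)
    all_pos = np.vstack([pop.positions, opp])
    all_fit = np.concatenate([pop.fitness, opp_fit])
    all_stag = np.concatenate([pop.stagnation, pop.stagnation])
    keep = np.argsort(all_fit, kind="stable")[: len(pop.fitness)]
    new = Population(
        positions=all_pos[keep], fitness=all_fit[keep],
        best_position=pop.best_position, best_fitness=pop.best_fitness,
        iteration=pop.iteration, stagnation=all_stag[keep],
    )
    new._update_best()
    return new


def bslo_iteration(
    pop: Population, config: OptimizerConfig, objective: Objective,
    rng: np.random.Generator,
) -> Population:
    """One BSLO generation applying the five predation strategies."""
    lo, hi = config.bounds
    n, d = pop.positions.shape
    sp = config.strategy_params
    t_frac = min(pop.iteration / max(config.max_iterations, 1), 1.0)
    best = pop.best_position

    # directional switching: per-leech explore/exploit choice, explore-heavy
    # early, exploit-heavy late
    p_explore = (1.0 - t_frac) ** sp.switching_power
    explore = rng.random(n) < p_explore

    r1 = rng.random((n, d))
    r2 = rng.random((n, d))
    partners = rng.integers(0, n, size=(2, n))
    diff = pop.positions[partners[0]] - pop.positions[partners[1]]
    # directional exploration: advance on the best plus a peer-difference kick
    explored = pop.positions + r1 * (best - pop.positions) + (2.0 * r2 - 1.0) * diff
    # directional exploitation: contracting orbit around the best
    radius = sp.exploitation_step * (1.0 - t_frac)
    exploited = best + radius * (2.0 * r1 - 1.0) * np.abs(best - pop.positions)

    cand = np.where(explore[:, None], explored, exploited)

    # non-directional search: random relocation of a small subset
    n_move = int(round(sp.nondirectional_fraction * n))
    if n_move > 0:
        idx = rng.choice(n, size=n_move, replace=False)
        cand[idx] = rng.uniform(lo, hi, size=(n_move, d))

    # retracing: stagnant leeches restart from a fresh random position
    stuck = np.flatnonzero(pop.stagnation >= sp.retracing_trigger_count)
    if len(stuck) > 0:
        cand[stuck] = rng.uniform(lo, hi, size=(len(stuck), d))

    cand = np.clip(cand, lo, hi)
    cand_fit = np.asarray(objective(cand), dtype=float)

    # greedy replacement; retraced leeches always take their fresh position
    improved = cand_fit <= pop.fitness
    accept = improved.copy()
    accept[stuck] = True
    positions = np.where(accept[:, None], cand, pop.positions)
    fitness = np.where(accept, cand_fit, pop.fitness)

    stagnation = np.where(cand_fit < pop.fitness, 0, pop.stagnation + 1)
    stagnation[stuck] = 0

    new = Population(
        positions=positions, fitness=fitness,
        best_position=pop.best_position, best_fitness=pop.best_fitness,
        iteration=pop.iteration + 1, stagnation=stagnation,
    )
    new._update_best()
    return new


def optimize(
    objective: Objective,
    config: OptimizerConfig,
    iteration_hook: Callable[[int], None] | None = None,
    initial_candidates: np.ndarray | None = None,
) -> OptimizationResult:
    """Run BSLO or IBSLO; returns best solution plus the per-iteration trace.

    bslo: uniform random init, then the five-strategy generation loop.
    ibslo: cubic chaotic init, then each generation is followed by a dynamic
    opposition-based learning step.  ``iteration_hook`` (if given) is called
    with the iteration index before each generation — used by callers whose
    objective varies over iterations (e.g. dynamically weighted fitness).
    ``initial_candidates`` rows (if given) replace the first rows of the
    initial population — a warm start with caller-known reference solutions.
    """
    evals = 0

    def counted(X: np.ndarray) -> np.ndarray:
        nonlocal evals
        X = np.atleast_2d(X)
        evals += len(X)
        return np.asarray(objective(X), dtype=float)

    rng = np.random.default_rng(config.seed)
    if config.variant == "ibslo":
        pop = initialize_population_chaotic(config, counted)
    else:
        pop = _initialize_uniform(config, counted, rng)

    if initial_candidates is not None:
        lo, hi = config.bounds
        seeds = np.clip(np.atleast_2d(initial_candidates), lo, hi)
        k = min(len(seeds), config.population_size)
        pop.positions[:k] = seeds[:k]
        pop.fitness[:k] = counted(seeds[:k])
        i = int(np.argmin(pop.fitness))
        pop.best_position = pop.positions[i].copy()
        pop.best_fitness = float(pop.fitness[i])

    history = np.empty(config.max_iterations)
    for t in range(config.max_iterations):
        if iteration_hook is not None:
            iteration_hook(t)
        pop = bslo_iteration(pop, config, counted, rng)
        if config.variant == "ibslo":
            pop = dynamic_obl_step(pop, counted, rng, config.obl_probability)
        history[t] = pop.best_fitness

    return OptimizationResult(
        best_position=pop.best_position.copy(),
        best_fitness=float(pop.best_fitness),
        history=history, evaluations=evals,
    )


def as_batch_objective(f: Callable[[np.ndarray], float]) -> Objective:
    """Lift a scalar objective ``f(x) -> float`` to the batch interface."""

    def batched(X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return np.array([f(x) for x in X], dtype=float)

    return batched
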