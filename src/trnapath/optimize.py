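"""Differential-evolution tuning of the six scaling factors.

The six weights are tuned against a balanced sensitivity/specificity
objective evaluated under take-one-out scoring:

``objective = 2 - ((sens + spec) - |sens - spec|) = 2 - 2*min(sens, spec)``

taken at the crossover of the LOO sweep, so the objective is 0 when both
are perfect and 2 when either collapses.  The optimizer is the classic
DE/rand/1/bin scheme (mutation factor F = 0.7, crossover rate CR = 0.9)
with greedy selection, clipped to per-factor bounds and fully determined
by its seed.  Different seeds legitimately land on different near-optimal
factor sets; multi-seed runs report all of them and select the lowest
objective.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import yaml

from .evaluation import LOOEvaluator, sweep
from .scoring import FACTOR_NAMES, ConfigurationError, ScalingFactors

__all__ = [
    "DE_F",
    "DE_CR",
    "DEFAULT_BOUNDS",
    "OptimizationConfig",
    "OptimizationResult",
    "objective_value",
    "make_objective",
    "differential_evolution",
    "optimize",
    "load_config",
]

DE_F = 0.7
DE_CR = 0.9

#: Generous envelope around plausible weights; var_hx_scal may go negative
#: so the optimizer can invert the history term, the three structurally
#: positive weights are bounded away from zero.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "var_hx_scal": (-5.0, 20.0),
    "cons_scal": (0.0, 20.0),
    "var_hx_cons_scal": (1e-6, 20.0),
    "SS_scal": (1e-6, 20.0),
    "Pos_scal": (1e-6, 20.0),
    "base_scal": (0.0, 20.0),
}


@dataclass
class OptimizationConfig:
    bounds: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDS)
    )
    population_size: int = 15
    max_generations: int = 30
    seed: int = 0
    convergence_tolerance: float = 0.0  # 0 disables early stopping

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ConfigurationError("population_size must be >= 4")
        missing = set(FACTOR_NAMES) - set(self.bounds)
        if missing:
            raise ConfigurationError(f"bounds missing factors {sorted(missing)}")
        for name, (lo, hi) in self.bounds.items():
            if not lo < hi:
                raise ConfigurationError(f"bounds for {name}: low must be < high")

    def bound_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([self.bounds[n][0] for n in FACTOR_NAMES])
        hi = np.array([self.bounds[n][1] for n in FACTOR_NAMES])
        return lo, hi


@dataclass
class OptimizationResult:
    factors: ScalingFactors
    objective: float
    trace: list[float]  # best objective per generation, non-increasing
    seed: int
    n_evaluations: int


def objective_value(sensitivity: float, specificity: float) -> float:
    """2 - ((sens + spec) - |sens - spec|); minimal when both are maximal."""
    return 2.0 - ((sensitivity + specificity) - abs(sensitivity - specificity))


def make_objective(evaluator: LOOEvaluator) -> Callable[[np.ndarray], float]:
    """Objective over a factor vector: balanced LOO performance at the crossover."""

    def objective(x: np.ndarray) -> float:
        factors = ScalingFactors.from_array(x)
        scores = evaluator.scores(factors)
        result = sweep(scores, evaluator.labels)
        sens, spec = result.at_crossover()
        return objective_value(sens, spec)

    return objective


def differential_evolution(
    func: Callable[[np.ndarray], float],
    bounds: Sequence[tuple[float, float]] | dict[str, tuple[float, float]],
    *,
    population_size: int = 15,
    max_generations: int = 30,
    seed: int = 0,
    convergence_tolerance: float = 0.0,
    f: float = DE_F,
    cr: float = DE_CR,
) -> tuple[np.ndarray, float, list[float], int]:
    """Classic DE/rand/1/bin with greedy selection, deterministic given seed.

    Returns (best vector, best objective, per-generation best trace,
    number of objective evaluations).  The trace starts at the initial
    population's best and is non-increasing because a member is only
    replaced by a trial that is at least as good.
    """
    if isinstance(bounds, dict):
        bounds = [bounds[n] for n in FACTOR_NAMES]
    lo = np.array([b[0] for b in bounds], dtype=float)
    hi = np.array([b[1] for b in bounds], dtype=float)
    if np.any(lo >= hi):
        raise ConfigurationError("each bound must satisfy low < high")
    if population_size < 4:
        raise ConfigurationError("population_size must be >= 4")
    dim = lo.size
    rng = np.random.default_rng(seed)

    pop = lo + rng.random((population_size, dim)) * (hi - lo)
    fitness = np.array([func(x) for x in pop])
    n_evals = population_size
    trace = [float(fitness.min())]

    for _ in range(max_generations):
        for i in range(population_size):
            candidates = [j for j in range(population_size) if j != i]
            a, b, c = rng.choice(candidates, size=3, replace=False)
            mutant = np.clip(pop[a] + f * (pop[b] - pop[c]), lo, hi)
            mask = rng.random(dim) < cr
            mask[rng.integers(dim)] = True  # guarantee at least one gene crosses
            trial = np.where(mask, mutant, pop[i])
            ft = func(trial)
            n_evals += 1
            if ft <= fitness[i]:
                pop[i] = trial
                fitness[i] = ft
        trace.append(float(fitness.min()))
        if convergence_tolerance > 0 and fitness.std() <= convergence_tolerance:
            break

    best = int(np.argmin(fitness))
    return pop[best].copy(), float(fitness[best]), trace, n_evals


def optimize(
    config: OptimizationConfig,
    objective: Callable[[np.ndarray], float],
) -> OptimizationResult:
    """Run DE under ``config`` against an objective over factor vectors."""
    x, fx, trace, n_evals = differential_evolution(
        objective,
        config.bounds,
        population_size=config.population_size,
        max_generations=config.max_generations,
        seed=config.seed,
        convergence_tolerance=config.convergence_tolerance,
    )
    return OptimizationResult(
        factors=ScalingFactors.from_array(x),
        objective=fx,
        trace=trace,
        seed=config.seed,
        n_evaluations=n_evals,
    )


def load_config(path) -> tuple[OptimizationConfig, list[int]]:
    """Read a YAML config; returns the config plus the list of seeds to run.

    Recognized keys: ``bounds`` (factor -> [low, high]), ``population_size``,
    ``max_generations``, ``convergence_tolerance``, and ``seed`` or ``seeds``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("optimization config must be a mapping")
    bounds = dict(DEFAULT_BOUNDS)
    for name, pair in (raw.get("bounds") or {}).items():
        if name not in FACTOR_NAMES:
            raise ConfigurationError(f"unknown factor {name!r} in bounds")
        bounds[name] = (float(pair[0]), float(pair[1]))
    seeds = raw.get("seeds")
    if seeds is None:
        seeds = [int(raw.get("seed", 0))]
    seeds = [int(s) for s in seeds]
    if not seeds:
        raise ConfigurationError("empty seed list")
    config = OptimizationConfig(
        bounds=bounds,
        population_size=int(raw.get("population_size", 15)),
        max_generations=int(raw.get("max_generations", 30)),
        seed=seeds[0],
        convergence_tolerance=float(raw.get("convergence_tolerance", 0.0)),
    )
    return config, seeds
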