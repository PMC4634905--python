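"""Seeded genetic algorithm over binary or simplex-constrained chromosomes.

One engine serves both search problems in this package: the wrapper feature
selection (binary chromosomes marking included dimensions) and ensemble
weight tuning (nonnegative real weights summing to 1).  The generational
scheme follows common GA-toolbox conventions: rank-based fitness scaling,
stochastic universal sampling, elitism, uniform (scattered) crossover for
binary genes / blend crossover for reals, and per-gene mutation.  The run
stops when the change of best fitness between consecutive generations falls
below ``fitness_tolerance`` or ``max_generations`` is reached.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

logger = logging.getLogger(__name__)

__all__ = ["GAConfig", "GAResult", "ga_maximize"]


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 100
    max_generations: int = 60
    fitness_tolerance: float = 1e-6
    elitism_count: int = 2
    crossover_fraction: float = 0.8
    mutation_rate: float = 0.01
    mutation_sigma: float = 0.1  # Gaussian mutation scale for simplex genes
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ConfigurationError("population_size must be >= 2")
        if self.max_generations < 1:
            raise ConfigurationError("max_generations must be >= 1")
        if self.fitness_tolerance < 0:
            raise ConfigurationError("fitness_tolerance must be >= 0")
        if not 0 <= self.crossover_fraction <= 1:
            raise ConfigurationError("crossover_fraction must be in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise ConfigurationError("mutation_rate must be in [0, 1]")
        if not 0 <= self.elitism_count < self.population_size:
            raise ConfigurationError("elitism_count must be in [0, population_size)")


@dataclass
class GAResult:
    best_chromosome: np.ndarray
    best_fitness: float
    trace: list[float] = field(default_factory=list)  # best-so-far per generation
    generations_run: int = 0
    n_evaluations: int = 0


def _repair_simplex(pop: np.ndarray) -> np.ndarray:
    """Clip negatives to 0 and renormalize each row to sum 1; all-zero rows become uniform."""
    pop = np.clip(pop, 0.0, None)
    sums = pop.sum(axis=1, keepdims=True)
    zero = sums[:, 0] == 0
    if zero.any():
        pop[zero] = 1.0 / pop.shape[1]
        sums = pop.sum(axis=1, keepdims=True)
    return pop / sums


def _sus(weights: np.ndarray, n_picks: int, rng: np.random.Generator) -> np.ndarray:
    """Stochastic universal sampling: n_picks indices with probability proportional to weights."""
    cum = np.cumsum(weights)
    total = cum[-1]
    step = total / n_picks
    start = rng.uniform(0, step)
    pointers = start + step * np.arange(n_picks)
    idx = np.searchsorted(cum, pointers, side="right")
    return np.minimum(idx, len(weights) - 1)


def ga_maximize(fitness, encoding: str, length: int, config: GAConfig = GAConfig()) -> GAResult:
    """Maximize ``fitness(chromosome)`` over binary or simplex chromosomes.

    Parameters
    ----------
    fitness
        Callable on a 1-D chromosome array; must be deterministic for a given
        chromosome (callers with stochastic objectives fix their internal
        folds per run).  Non-finite fitness values are treated as -inf.
    encoding
        ``"binary"`` — genes in {0, 1}; ``"simplex"`` — nonnegative reals
        summing to 1 (guaranteed for every evaluated chromosome).
    length
        Chromosome length.
    """
    if encoding not in ("binary", "simplex"):
        raise ConfigurationError(f"unknown encoding {encoding!r}")
    if length < 1:
        raise ConfigurationError("chromosome length must be >= 1")
    rng = np.random.default_rng(config.seed)
    P = config.population_size

    if encoding == "binary":
        pop = (rng.random((P, length)) < 0.5).astype(np.int8)
    else:
        pop = _repair_simplex(rng.random((P, length)))

    cache: dict[bytes, float] = {}
    n_evals = 0

    def evaluate(rows: np.ndarray) -> np.ndarray:
        nonlocal n_evals
        out = np.empty(rows.shape[0])
        for i, chrom in enumerate(rows):
            key = np.ascontiguousarray(chrom).tobytes()
            if key not in cache:
                val = float(fitness(chrom.copy()))
                if not np.isfinite(val):
                    logger.warning("non-finite fitness for a chromosome; assigning -inf")
                    val = -np.inf
                cache[key] = val
                n_evals += 1
            out[i] = cache[key]
        return out

    fit = evaluate(pop)
    trace: list[float] = []
    best_idx = int(np.argmax(fit))
    best_chrom, best_fit = pop[best_idx].copy(), float(fit[best_idx])
    trace.append(best_fit)

    gen = 1
    while gen < config.max_generations:
        order = np.argsort(-fit, kind="stable")
        elite = pop[order[: config.elitism_count]].copy()

        n_children = P - config.elitism_count
        n_cross = int(round(config.crossover_fraction * n_children))
        n_mut = n_children - n_cross

        # rank scaling (1/sqrt(rank)) keeps selection pressure independent of
        # the fitness scale; -inf chromosomes get the lowest ranks anyway
        ranks = np.empty(P)
        ranks[order] = np.arange(1, P + 1)
        weights = 1.0 / np.sqrt(ranks)
        picks = _sus(weights, 2 * n_cross + n_mut, rng)
        parents = pop[rng.permutation(picks)]

        children = []
        if n_cross:
            p1 = parents[:n_cross]
            p2 = parents[n_cross : 2 * n_cross]
            if encoding == "binary":
                mask = rng.random((n_cross, length)) < 0.5
                children.append(np.where(mask, p1, p2))
            else:
                # extrapolating blend (BLX-0.5): children may land outside the
                # parents' segment, which after clipping/renormalization lets
                # the search reach simplex vertices
                u = rng.uniform(-0.5, 1.5, (n_cross, length))
                children.append(u * p1 + (1.0 - u) * p2)
        if n_mut:
            base = parents[2 * n_cross :].copy()
            if encoding == "binary":
                flips = rng.random((n_mut, length)) < config.mutation_rate
                base = np.where(flips, 1 - base, base)
            else:
                base = base + rng.normal(0.0, config.mutation_sigma, (n_mut, length))
            children.append(base)

        pop = np.vstack([elite] + children) if children else elite
        if encoding == "binary":
            pop = pop.astype(np.int8)
        else:
            pop = _repair_simplex(pop)

        fit = evaluate(pop)
        gen += 1
        gen_best = int(np.argmax(fit))
        if fit[gen_best] > best_fit:
            best_chrom, best_fit = pop[gen_best].copy(), float(fit[gen_best])
        trace.append(best_fit)
        if abs(trace[-1] - trace[-2]) < config.fitness_tolerance:
            break

    return GAResult(
        best_chromosome=best_chrom,
        best_fitness=best_fit,
        trace=trace,
        generations_run=gen,
        n_evaluations=n_evals,
    )
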