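"""Genetic-algorithm search over per-environment training subsets.

The search space is a product of subsets: one size-nj subset of the
candidate population per environment.  A generational GA with tournament
selection, per-environment union crossover, single-swap mutation and
elitism climbs a CD criterion.  A floor on the number of iterations
(default 12,000) is enforced before the patience-based stopping rule, to
reduce the risk of settling in a poor local optimum; fitness values are
memoized, and when the whole design space has provably been evaluated the
incumbent is the global optimum and the search stops early.

``random_design`` provides the random-sampling baseline used throughout the
evaluation experiments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .criteria import CDScorer, CriterionSpec
from .genotypes import GenomicRelationship
from .mge_model import TrainingDesign

__all__ = ["GAConfig", "OptimizationResult", "random_design", "optimize_design"]

_EXHAUSTION_CHECK_LIMIT = 1_000_000  # only track exhaustion for small spaces


@dataclass
class GAConfig:
    """Tuning knobs of the subset GA.

    ``min_iterations`` is the floor before the stopping rule applies;
    ``patience`` is the length of the non-improving streak that then stops
    the search.  ``mutation_rate`` is the per-environment probability of
    swapping one selected index for an unselected one.  ``local_search_swaps``
    enables an optional greedy swap refinement of the incumbent each
    iteration (off by default).
    """

    seed: int
    population_size: int = 50
    min_iterations: int = 12_000
    patience: int = 500
    elite_count: int = 1
    tournament_size: int = 3
    mutation_rate: float = 0.1
    local_search_swaps: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.min_iterations < 1:
            raise ValueError("min_iterations must be >= 1")
        if not 0 <= self.mutation_rate <= 1:
            raise ValueError("mutation_rate must lie in [0, 1]")
        if self.elite_count < 0 or self.elite_count >= self.population_size:
            raise ValueError("elite_count must lie in [0, population_size)")


@dataclass
class OptimizationResult:
    best_design: TrainingDesign
    best_score: float
    trace: np.ndarray
    iterations_run: int
    seed: int
    n_evaluations: int = 0
    space_exhausted: bool = False


def random_design(
    ncp: int, sizes: tuple[int, ...], seed: int | np.random.Generator
) -> TrainingDesign:
    """Draw each environment's subset uniformly without replacement.

    Environments are independent, so the same genotype may be trained in
    several environments.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if any(n < 1 or n > ncp for n in sizes):
        raise ValueError("each environment size must lie in [1, ncp]")
    return TrainingDesign([rng.choice(ncp, size=n, replace=False) for n in sizes])


def _design_space_size(ncp: int, sizes: tuple[int, ...]) -> int:
    total = 1
    for n in sizes:
        total *= math.comb(ncp, n)
        if total > _EXHAUSTION_CHECK_LIMIT:
            return total
    return total


def _mutate(subset: np.ndarray, ncp: int, rng: np.random.Generator) -> np.ndarray:
    """Swap one selected index for one unselected index."""
    if subset.size == ncp:
        return subset
    out = subset.copy()
    pos = rng.integers(subset.size)
    pool = np.setdiff1d(np.arange(ncp), subset, assume_unique=False)
    out[pos] = pool[rng.integers(pool.size)]
    return out


def optimize_design(
    K: GenomicRelationship,
    sizes: tuple[int, ...],
    criterion: CriterionSpec | None = None,
    cfg: GAConfig | None = None,
) -> OptimizationResult:
    """Search for a training design maximizing a CD criterion.

    Deterministic given (seed, config, inputs).  The returned trace of
    incumbent scores is non-decreasing by elitism.
    """
    cfg = cfg or GAConfig(seed=0)
    criterion = criterion or CriterionSpec()
    ncp = K.n_genotypes
    sizes = tuple(int(n) for n in sizes)
    if any(n < 1 or n > ncp for n in sizes):
        raise ValueError("infeasible sizes for this candidate population")
    scorer = CDScorer(K, len(sizes), criterion)
    rng = np.random.default_rng(cfg.seed)

    space = _design_space_size(ncp, sizes)
    track_exhaustion = space <= _EXHAUSTION_CHECK_LIMIT

    cache: dict[tuple, float] = {}

    def fitness(subsets: list[np.ndarray]) -> float:
        key = tuple(tuple(sorted(s.tolist())) for s in subsets)
        val = cache.get(key)
        if val is None:
            val = scorer(TrainingDesign([s.copy() for s in subsets]))
            if not np.isfinite(val):
                raise ValueError("criterion returned a non-finite score")
            cache[key] = val
        return val

    population = [
        [rng.choice(ncp, size=n, replace=False) for n in sizes]
        for _ in range(cfg.population_size)
    ]
    scores = np.array([fitness(ind) for ind in population])

    best_idx = int(np.argmax(scores))
    best = [s.copy() for s in population[best_idx]]
    best_score = float(scores[best_idx])

    trace = [best_score]
    streak = 0
    iteration = 0
    exhausted = track_exhaustion and len(cache) >= space

    while not exhausted:
        iteration += 1
        order = np.argsort(scores)[::-1]
        elites = [[s.copy() for s in population[i]] for i in order[: cfg.elite_count]]

        children = list(elites)
        while len(children) < cfg.population_size:
            # tournament selection of two parents
            parents = []
            for _ in range(2):
                contenders = rng.integers(cfg.population_size, size=cfg.tournament_size)
                parents.append(population[contenders[np.argmax(scores[contenders])]])
            child = []
            for j, n in enumerate(sizes):
                union = np.union1d(parents[0][j], parents[1][j])
                sub = union if union.size == n else rng.choice(union, size=n, replace=False)
                if rng.random() < cfg.mutation_rate:
                    sub = _mutate(np.asarray(sub), ncp, rng)
                child.append(np.asarray(sub))
            children.append(child)

        population = children
        scores = np.array([fitness(ind) for ind in population])

        if cfg.local_search_swaps > 0:
            i_best = int(np.argmax(scores))
            cand = [s.copy() for s in population[i_best]]
            for _ in range(cfg.local_search_swaps):
                j = int(rng.integers(len(sizes)))
                trial = [s.copy() for s in cand]
                trial[j] = _mutate(trial[j], ncp, rng)
                if fitness(trial) > fitness(cand):
                    cand = trial
            if fitness(cand) > scores[i_best]:
                population[i_best] = cand
                scores[i_best] = fitness(cand)

        gen_best = int(np.argmax(scores))
        if scores[gen_best] > best_score:
            best_score = float(scores[gen_best])
            best = [s.copy() for s in population[gen_best]]
            streak = 0
        else:
            streak += 1
        trace.append(best_score)

        exhausted = track_exhaustion and len(cache) >= space
        if exhausted:
            break
        if iteration >= cfg.min_iterations and streak >= cfg.patience:
            break

    if exhausted:
        # every design has been scored: report the certified global optimum
        key, val = max(cache.items(), key=lambda kv: kv[1])
        if val > best_score:
            best_score = float(val)
            best = [np.asarray(s, dtype=np.int64) for s in key]
            trace[-1] = best_score

    return OptimizationResult(
        best_design=TrainingDesign(best),
        best_score=best_score,
        trace=np.asarray(trace),
        iterations_run=iteration,
        seed=cfg.seed,
        n_evaluations=len(cache),
        space_exhausted=exhausted,
    )
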