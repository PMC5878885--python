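"""Genetic search over complaint-specification masks.

Candidate solutions are length-n bit strings (one bit per specific
complaint).  Each generation, parents are chosen by tournament selection,
recombined by uniform crossover (contiguity carries no meaning for
complaint bits, so positional independence is appropriate), offspring are
bit-flip mutated, and the top N of parents plus offspring survive — a
(mu + lambda) scheme with lambda = N, which realizes elitist retention and
guarantees a non-decreasing best fitness.

Because the cross-validation folds are fixed for a whole run, fitness is a
pure function of the mask, so evaluations are memoized; the cache can also
be shared with :func:`exhaustive_search` on small instances.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np

from .data_model import Cohort, SpecificationMask
from .errors import SearchSpaceError, ValidationError
from .fitness import cv_fitness

#: control parameters established for this application (population 40,
#: 100 generations, tournament k=3, uniform crossover at rate 0.6 with
#: mixing ratio 0.2, per-individual mutation rate 0.2, per-bit flip 0.05)
DEFAULTS = dict(
    population_size=40,
    generations=100,
    tournament_k=3,
    crossover_rate=0.6,
    mixing_ratio=0.2,
    mutation_rate=0.2,
    bit_flip_rate=0.05,
)


@dataclass
class GAConfig:
    population_size: int = 40
    generations: int = 100
    tournament_k: int = 3
    crossover_rate: float = 0.6
    mixing_ratio: float = 0.2
    mutation_rate: float = 0.2
    bit_flip_rate: float = 0.05
    mode: str = "flattened"
    k_folds: int = 5
    rng_seed: int = 0
    fold_seed: int = 0
    ridge: float = 1e-6
    hall_of_fame_size: int = 20
    cv_tol: float = 1e-4

    def __post_init__(self) -> None:
        for name in ("crossover_rate", "mixing_ratio", "mutation_rate", "bit_flip_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be a probability, got {v}")
        if self.population_size < 2:
            raise ValidationError("population_size must be >= 2")
        if self.tournament_k < 1 or self.tournament_k > self.population_size:
            raise ValidationError("tournament_k must be in [1, population_size]")
        if self.generations < 0:
            raise ValidationError("generations must be >= 0")
        if self.mode not in ("flattened", "hierarchical"):
            raise ValidationError(f"GA mode must be flattened or hierarchical, got {self.mode!r}")


@dataclass
class GenerationStats:
    generation: int
    best: float
    mean: float


@dataclass
class GAResult:
    best_mask: SpecificationMask
    best_fitness: float
    history: list[GenerationStats]
    hall_of_fame: list[tuple[SpecificationMask, float]]
    evaluations: int
    config: GAConfig | None = None

    def to_dict(self) -> dict:
        return {
            "best_mask": self.best_mask.to_string(),
            "best_fitness": self.best_fitness,
            "history": [asdict(h) for h in self.history],
            "hall_of_fame": [
                {"mask": m.to_string(), "fitness": f} for m, f in self.hall_of_fame
            ],
            "evaluations": self.evaluations,
            "config": asdict(self.config) if self.config else None,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# --------------------------------------------------------------------------
# Operators
# --------------------------------------------------------------------------

def init_population(n: int, size: int, rng: np.random.Generator) -> list[SpecificationMask]:
    """``size`` random masks of length ``n``; each bit an independent fair coin."""
    if n < 1 or size < 2:
        raise ValidationError("need n >= 1 and population size >= 2")
    bits = (rng.random((size, n)) < 0.5).astype(np.uint8)
    return [SpecificationMask(row) for row in bits]


def tournament_select(
    population: Sequence[SpecificationMask],
    fitnesses: Sequence[float],
    k: int,
    rng: np.random.Generator,
) -> SpecificationMask:
    """Draw k members with replacement; return the fittest (ties uniform)."""
    if len(population) == 0:
        raise ValidationError("cannot select from an empty population")
    if len(population) != len(fitnesses):
        raise ValidationError("fitnesses must align with the population")
    fit = np.asarray(fitnesses, dtype=float)
    idx = rng.integers(0, len(population), size=k)
    drawn = fit[idx]
    winners = idx[drawn == drawn.max()]
    return population[int(winners[rng.integers(len(winners))])]


def uniform_crossover(
    parent_a: SpecificationMask,
    parent_b: SpecificationMask,
    mixing_ratio: float,
    rng: np.random.Generator,
) -> tuple[SpecificationMask, SpecificationMask]:
    """Exchange each bit position between the children with prob ``mixing_ratio``."""
    if len(parent_a) != len(parent_b):
        raise ValidationError("parents must have equal length")
    swap = rng.random(len(parent_a)) < mixing_ratio
    a, b = parent_a.bits.copy(), parent_b.bits.copy()
    a[swap], b[swap] = parent_b.bits[swap], parent_a.bits[swap]
    return SpecificationMask(a), SpecificationMask(b)


def bit_flip_mutate(
    mask: SpecificationMask, bit_flip_rate: float, rng: np.random.Generator
) -> SpecificationMask:
    """Invert each bit independently with prob ``bit_flip_rate``: excluded
    complaints become selected and vice versa."""
    flips = rng.random(len(mask)) < bit_flip_rate
    return SpecificationMask(mask.bits ^ flips.astype(np.uint8))


def _rank_key(mask: SpecificationMask, fitness: float):
    # fitness desc, then fewer selected complaints, then lexicographic bits
    return (-fitness, mask.popcount, mask.to_string())


# --------------------------------------------------------------------------
# Search drivers
# --------------------------------------------------------------------------

def _make_evaluator(
    cohort: Cohort, config: GAConfig, cache: dict | None
) -> tuple[Callable[[SpecificationMask], float], dict, list[int]]:
    cache = {} if cache is None else cache
    misses = [0]

    def evaluate(mask: SpecificationMask) -> float:
        key = mask.bits.tobytes()
        if key not in cache:
            cache[key] = cv_fitness(
                cohort, mask, config.mode, k=config.k_folds,
                fold_seed=config.fold_seed, ridge=config.ridge,
                tol=config.cv_tol,
            ).auc
            misses[0] += 1
        return cache[key]

    return evaluate, cache, misses


def evolve(
    cohort: Cohort,
    config: GAConfig,
    fitness_cache: dict | None = None,
    progress: Callable[[GenerationStats], None] | None = None,
) -> GAResult:
    """Run the genetic search; fully reproducible from (rng_seed, fold_seed).

    ``fitness_cache`` (mask bytes -> fitness) may be shared across runs on
    the same cohort/fold configuration; fitness is a pure function of the
    mask there, so sharing changes cost, never results.
    """
    n = cohort.hierarchy.n
    rng = np.random.default_rng(config.rng_seed)
    evaluate, _, misses = _make_evaluator(cohort, config, fitness_cache)

    population = init_population(n, config.population_size, rng)
    fitnesses = [evaluate(m) for m in population]
    seen: dict[bytes, tuple[SpecificationMask, float]] = {
        m.bits.tobytes(): (m, f) for m, f in zip(population, fitnesses)
    }

    order = sorted(range(len(population)),
                   key=lambda i: _rank_key(population[i], fitnesses[i]))
    population = [population[i] for i in order]
    fitnesses = [fitnesses[i] for i in order]
    history = [GenerationStats(0, fitnesses[0], float(np.mean(fitnesses)))]
    if progress:
        progress(history[-1])

    N = config.population_size
    for gen in range(1, config.generations + 1):
        offspring: list[SpecificationMask] = []
        while len(offspring) < N:
            pa = tournament_select(population, fitnesses, config.tournament_k, rng)
            pb = tournament_select(population, fitnesses, config.tournament_k, rng)
            if rng.random() < config.crossover_rate:
                ca, cb = uniform_crossover(pa, pb, config.mixing_ratio, rng)
            else:
                ca, cb = pa, pb
            offspring.extend((ca, cb))
        offspring = offspring[:N]
        offspring = [
            bit_flip_mutate(c, config.bit_flip_rate, rng)
            if rng.random() < config.mutation_rate else c
            for c in offspring
        ]
        off_fit = [evaluate(c) for c in offspring]
        for m, f in zip(offspring, off_fit):
            seen[m.bits.tobytes()] = (m, f)

        pool = list(zip(population + offspring, fitnesses + off_fit))
        pool.sort(key=lambda mf: _rank_key(*mf))
        population = [m for m, _ in pool[:N]]
        fitnesses = [f for _, f in pool[:N]]
        history.append(GenerationStats(gen, fitnesses[0], float(np.mean(fitnesses))))
        if progress:
            progress(history[-1])

    hof = sorted(seen.values(), key=lambda mf: _rank_key(*mf))
    hof = hof[: config.hall_of_fame_size]
    return GAResult(
        best_mask=population[0],
        best_fitness=fitnesses[0],
        history=history,
        hall_of_fame=[(m, f) for m, f in hof],
        evaluations=misses[0],
        config=config,
    )


@dataclass
class ExhaustiveResult:
    best_mask: SpecificationMask
    best_fitness: float
    table: dict[str, float]  # mask string -> fitness, all 2^n masks


def exhaustive_search(
    cohort: Cohort,
    mode: str,
    k_folds: int = 5,
    fold_seed: int = 0,
    ridge: float = 1e-6,
    max_n: int = 16,
    cv_tol: float = 1e-4,
    fitness_cache: dict | None = None,
) -> ExhaustiveResult:
    """Evaluate every one of the 2^n masks (oracle for the stochastic search)."""
    n = cohort.hierarchy.n
    if n > max_n:
        raise SearchSpaceError(
            f"exhaustive search refused: n={n} complaints exceeds the cap "
            f"max_n={max_n} (2^{n} masks)"
        )
    config = GAConfig(mode=mode, k_folds=k_folds, fold_seed=fold_seed,
                      ridge=ridge, cv_tol=cv_tol)
    evaluate, _, _ = _make_evaluator(cohort, config, fitness_cache)
    shifts = np.arange(n)
    table: dict[str, float] = {}
    best: tuple | None = None
    for code in range(2 ** n):
        mask = SpecificationMask(((code >> shifts) & 1).astype(np.uint8))
        f = evaluate(mask)
        table[mask.to_string()] = f
        key = _rank_key(mask, f)
        if best is None or key < best[0]:
            best = (key, mask, f)
    return ExhaustiveResult(best_mask=best[1], best_fitness=best[2], table=table)
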