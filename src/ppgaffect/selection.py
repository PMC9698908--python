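"""Wrapper feature selection: exhaustive search and a genetic algorithm.

A candidate feature subset is a bitstring ("chromosome") over the feature
list, a '1' meaning the feature is kept.  Fitness is classification accuracy
of the downstream classifier under the configured validation scheme.  For
n ≤ ~15 features every one of the 2^n − 1 non-empty subsets can be scored
(full search); for larger sets a genetic algorithm — fitness-proportional
parent selection, one-point crossover, per-bit mutation, elitism and an
early-stopping patience — searches the space.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Sequence

import numpy as np

FULL_SEARCH_GUARD = 20


@dataclass
class Chromosome:
    """Bitstring over the feature set; fitness is accuracy in [0, 1]."""

    bits: tuple[int, ...]
    fitness: float | None = None

    @property
    def subset(self) -> tuple[int, ...]:
        return tuple(i for i, b in enumerate(self.bits) if b)

    @property
    def bitstring(self) -> str:
        return "".join(map(str, self.bits))


@dataclass
class GAConfig:
    population_size: int = 50
    n_generations: int = 100
    crossover_prob: float = 0.8
    mutation_prob_per_bit: float | None = None  # default 1/n_features
    elitism_count: int = 1
    early_stop_patience: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        for name in ("crossover_prob", "mutation_prob_per_bit"):
            p = getattr(self, name)
            if p is not None and not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.elitism_count < 0 or self.elitism_count > self.population_size:
            raise ValueError("elitism_count out of range")


class MemoizedEvaluator:
    """Caches subset → accuracy so repeated subsets cost one evaluation.

    ``func`` maps a sorted tuple of feature indices to an accuracy in [0, 1].
    """

    def __init__(self, func: Callable[[tuple[int, ...]], float]):
        self._func = func
        self._cache: dict[tuple[int, ...], float] = {}
        self.n_evaluations = 0

    def __call__(self, subset: Sequence[int]) -> float:
        key = tuple(sorted(set(int(i) for i in subset)))
        if not key:
            raise ValueError("empty feature subset is not a valid candidate")
        if key not in self._cache:
            self._cache[key] = float(self._func(key))
            self.n_evaluations += 1
        return self._cache[key]


def evaluate_subset(evaluator: Callable[[tuple[int, ...]], float], subset: Sequence[int]) -> float:
    """Score one non-empty subset with the configured evaluator."""
    subset = tuple(subset)
    if len(subset) == 0:
        raise ValueError("empty feature subset is not a valid candidate")
    return float(evaluator(subset))


def _better(cand: tuple[float, int, str], best: tuple[float, int, str]) -> bool:
    """Tie-break: higher fitness, then smaller subset, then lexicographically
    smallest bitstring."""
    f_c, size_c, bits_c = cand
    f_b, size_b, bits_b = best
    if f_c != f_b:
        return f_c > f_b
    if size_c != size_b:
        return size_c < size_b
    return bits_c < bits_b


def full_search(
    evaluator: Callable[[tuple[int, ...]], float], n_features: int
) -> tuple[tuple[int, ...], float, list[dict]]:
    """Evaluate every non-empty subset of ``n_features`` features.

    Returns (best subset, best fitness, evaluation log).  Refuses more than
    20 features — 2^n − 1 evaluations explode beyond that.
    """
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    if n_features > FULL_SEARCH_GUARD:
        raise ValueError(f"full search refused for n_features > {FULL_SEARCH_GUARD}; use ga_select")
    log: list[dict] = []
    best: tuple[float, int, str] | None = None
    best_subset: tuple[int, ...] = ()
    for size in range(1, n_features + 1):
        for subset in combinations(range(n_features), size):
            fitness = evaluate_subset(evaluator, subset)
            bits = "".join("1" if i in subset else "0" for i in range(n_features))
            log.append({"subset": subset, "bitstring": bits, "fitness": fitness})
            cand = (fitness, size, bits)
            if best is None or _better(cand, best):
                best, best_subset = cand, subset
    assert best is not None
    return best_subset, best[0], log


def _random_chromosome(n: int, rng: np.random.Generator) -> Chromosome:
    bits = rng.integers(0, 2, n)
    while not bits.any():
        bits = rng.integers(0, 2, n)
    return Chromosome(bits=tuple(int(b) for b in bits))


def _mutate(bits: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    out = bits.copy()
    flips = rng.random(len(out)) < p
    out[flips] = 1 - out[flips]
    # an all-zero offspring is not a valid candidate: re-mutate until non-empty
    while not out.any():
        flips = rng.random(len(out)) < max(p, 1.0 / len(out))
        out[flips] = 1 - out[flips]
    return out


def _roulette_pick(scaled: np.ndarray, rng: np.random.Generator) -> int:
    total = scaled.sum()
    if total <= 0:
        return int(rng.integers(0, len(scaled)))
    return int(rng.choice(len(scaled), p=scaled / total))


def ga_select(
    evaluator: Callable[[tuple[int, ...]], float],
    n_features: int,
    config: GAConfig | None = None,
) -> tuple[tuple[int, ...], float, list[dict]]:
    """Genetic-algorithm wrapper selection.

    Fitness-proportional (roulette) parent selection on min-max-scaled
    fitness, one-point crossover, per-bit flip mutation (default rate 1/n),
    elitism, and early stop when the best fitness has not improved for
    ``early_stop_patience`` generations.  Returns the overall best subset,
    its fitness and a per-generation log.
    """
    config = config or GAConfig()
    p_mut = config.mutation_prob_per_bit if config.mutation_prob_per_bit is not None else 1.0 / n_features
    rng = np.random.default_rng(config.seed)

    population = [_random_chromosome(n_features, rng) for _ in range(config.population_size)]
    for chrom in population:
        chrom.fitness = evaluate_subset(evaluator, chrom.subset)

    def key(c: Chromosome) -> tuple[float, int, str]:
        return (c.fitness, len(c.subset), c.bitstring)

    best = max(population, key=lambda c: (c.fitness, -len(c.subset)))
    log: list[dict] = []
    stall = 0
    for gen in range(config.n_generations):
        fitnesses = np.array([c.fitness for c in population])
        lo, hi = fitnesses.min(), fitnesses.max()
        scaled = (fitnesses - lo) / (hi - lo) if hi > lo else np.ones_like(fitnesses)

        elite = sorted(population, key=lambda c: (c.fitness, -len(c.subset)), reverse=True)
        offspring: list[Chromosome] = [
            Chromosome(bits=e.bits, fitness=e.fitness) for e in elite[: config.elitism_count]
        ]
        while len(offspring) < config.population_size:
            a = population[_roulette_pick(scaled, rng)]
            b = population[_roulette_pick(scaled, rng)]
            bits_a = np.array(a.bits)
            bits_b = np.array(b.bits)
            if n_features > 1 and rng.random() < config.crossover_prob:
                cut = int(rng.integers(1, n_features))
                bits_a, bits_b = (
                    np.concatenate([bits_a[:cut], bits_b[cut:]]),
                    np.concatenate([bits_b[:cut], bits_a[cut:]]),
                )
            for bits in (bits_a, bits_b):
                if len(offspring) >= config.population_size:
                    break
                child = Chromosome(bits=tuple(int(x) for x in _mutate(bits, p_mut, rng)))
                child.fitness = evaluate_subset(evaluator, child.subset)
                offspring.append(child)
        population = offspring

        gen_best = max(population, key=lambda c: (c.fitness, -len(c.subset)))
        if _better(key(gen_best), key(best)):
            best = gen_best
            stall = 0
        else:
            stall += 1
        log.append(
            {
                "generation": gen,
                "best_fitness": best.fitness,
                "gen_best_fitness": gen_best.fitness,
                "mean_fitness": float(np.mean([c.fitness for c in population])),
                "best_bitstring": best.bitstring,
            }
        )
        if stall >= config.early_stop_patience:
            break
    return best.subset, float(best.fitness), log
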