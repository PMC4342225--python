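"""Single-population genetic-algorithm wrapper for feature selection.

Chromosomes are binary inclusion vectors over the candidate features. Each
generation evaluates every new chromosome's classification Performance
(by inner cross-validation of the wrapped classifier), converts it to a
size-penalized fitness

    fitness = Performance - alpha * popcount / n        (alpha default 0.15)

and breeds offspring by repeated binary-tournament selection, two-point
crossover (rate 0.8) and bit-flip mutation (rate 0.01); parents and
offspring then compete and the best r survive ("best" population
replacement, which subsumes elitism). The run stops after
``max_generations`` evolutionary
cycles (default 100) or once the best fitness value has not changed for
``stagnation_patience`` consecutive generations (default 50).

Fitness evaluations are pure functions of (chromosome, data, fold split);
they may be farmed out to a worker pool, and results are reassembled in
submission order, so the outcome is bit-identical for any worker count —
the master/slave evaluation contract.
"""

from __future__ import annotations

import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field

import numpy as np

from .classifiers import InnerCVEvaluator, PerformanceRequest
from .data import Dataset

__all__ = [
    "GAConfig",
    "Population",
    "GAHistory",
    "GAEvaluationError",
    "initialize_population",
    "fitness",
    "tournament_select",
    "two_point_crossover",
    "mutate",
    "run_ga",
]

logger = logging.getLogger("gafs.ga")


class GAEvaluationError(RuntimeError):
    """A worker failed to evaluate a chromosome's Performance."""

    def __init__(self, chromosome: np.ndarray, cause: BaseException):
        self.chromosome = chromosome
        self.cause = cause
        super().__init__(
            f"fitness evaluation failed for chromosome with "
            f"{int(chromosome.sum())} bits set: {cause}")


@dataclass
class GAConfig:
    """Search-strategy parameters; defaults are the tool's published ones."""

    population_size: int = 100
    crossover_rate: float = 0.8
    mutation_rate: float = 0.01
    alpha: float = 0.15
    max_generations: int = 100
    stagnation_patience: int = 50
    seed: int = 0
    worker_count: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.crossover_rate <= 1.0
                and 0.0 <= self.mutation_rate <= 1.0):
            raise ValueError("crossover and mutation rates must lie in [0, 1]")
        if self.alpha < 0:
            raise ValueError("alpha must be >= 0")
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.stagnation_patience > self.max_generations:
            raise ValueError("stagnation_patience cannot exceed max_generations")
        if self.worker_count < 1:
            raise ValueError("worker_count must be >= 1")


@dataclass
class Population:
    members: np.ndarray          # (r, n) uint8
    fitness: np.ndarray | None   # (r,) or None before evaluation
    generation: int = 0

    @property
    def size(self) -> int:
        return self.members.shape[0]


@dataclass
class GAHistory:
    """Per-generation diagnostics plus the final outcome of a GA run."""

    generations: list[dict] = field(default_factory=list)
    best_chromosome: np.ndarray | None = None
    selected_indices: list[int] = field(default_factory=list)
    stop_reason: str = ""
    n_evaluations: int = 0

    @property
    def n_generations(self) -> int:
        """Evolutionary cycles run beyond the initial population."""
        return len(self.generations) - 1

    @property
    def stagnant_generations(self) -> int:
        return self.generations[-1]["stagnation"] if self.generations else 0


def initialize_population(n: int, config: GAConfig) -> Population:
    """Member 0 is all-ones; the rest are fair-coin bit vectors (repaired)."""
    if n < 1:
        raise ValueError("need at least one candidate feature")
    rng = np.random.default_rng(config.seed)
    members = (rng.random((config.population_size, n)) < 0.5).astype(np.uint8)
    members[0] = 1
    for i in range(1, config.population_size):
        if not members[i].any():
            members[i, rng.integers(0, n)] = 1
    return Population(members, None, 0)


def fitness(chromosome, performance: float, alpha: float, n: int) -> float:
    """Size-penalized fitness: Performance - alpha * popcount / n."""
    bits = np.asarray(chromosome)
    size = int(bits.sum())
    if size == 0:
        return float("-inf")
    if not np.isfinite(performance):
        raise ValueError("performance must be finite")
    return float(performance) - alpha * size / n


def _beats(pop: Population, i: int, j: int) -> bool:
    """True when member i outranks j: fitness, then smaller size, then index."""
    fi, fj = pop.fitness[i], pop.fitness[j]
    if fi != fj:
        return fi > fj
    si, sj = int(pop.members[i].sum()), int(pop.members[j].sum())
    if si != sj:
        return si < sj
    return i < j


def _best_index(pop: Population) -> int:
    best = 0
    for i in range(1, pop.size):
        if _beats(pop, i, best):
            best = i
    return best


def tournament_select(population: Population, rng: np.random.Generator
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Two independent binary tournaments, one per parent."""
    if population.fitness is None:
        raise ValueError("population must be evaluated before selection")
    parents = []
    for _ in range(2):
        a, b = rng.integers(0, population.size, size=2)
        winner = int(a) if _beats(population, int(a), int(b)) else int(b)
        parents.append(population.members[winner].copy())
    return parents[0], parents[1]


def two_point_crossover(p1, p2, rng: np.random.Generator, rate: float,
                        cuts: tuple[int, int] | None = None
                        ) -> tuple[np.ndarray, np.ndarray]:
    """Exchange the segment between two uniformly drawn cut points.

    With probability ``rate`` cut positions a < b are drawn uniformly from
    the n+1 gaps between genes and the slice [a:b) is swapped; otherwise
    the children are plain copies of the parents. ``cuts`` pins the cut
    points (used to reproduce worked examples).
    """
    p1 = np.asarray(p1, dtype=np.uint8)
    p2 = np.asarray(p2, dtype=np.uint8)
    if p1.shape != p2.shape:
        raise ValueError("parents must have equal length")
    c1, c2 = p1.copy(), p2.copy()
    if cuts is None:
        if rng.random() >= rate:
            return c1, c2
        a, b = np.sort(rng.choice(p1.size + 1, size=2, replace=False))
    else:
        a, b = cuts
        if not 0 <= a < b <= p1.size:
            raise ValueError(f"invalid cut points {cuts}")
    c1[a:b], c2[a:b] = p2[a:b].copy(), p1[a:b].copy()
    return c1, c2


def mutate(c, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Flip each bit independently with probability ``rate``; repair zeros."""
    bits = np.asarray(c, dtype=np.uint8).copy()
    flips = rng.random(bits.size) < rate
    bits[flips] ^= 1
    if not bits.any():
        bits[rng.integers(0, bits.size)] = 1
    return bits


def _evaluate_pending(pending: list[np.ndarray], perf_fn, worker_count: int
                      ) -> list[float]:
    def safe(bits: np.ndarray) -> float:
        try:
            return float(perf_fn(bits))
        except Exception as exc:  # noqa: BLE001 - reported with the chromosome
            raise GAEvaluationError(bits, exc) from exc

    if worker_count == 1 or len(pending) <= 1:
        return [safe(b) for b in pending]
    with ThreadPoolExecutor(max_workers=worker_count) as pool:
        return list(pool.map(safe, pending))


def run_ga(
    dataset: Dataset | None,
    config: GAConfig,
    request: PerformanceRequest | None = None,
    candidate_features=None,
    performance_fn=None,
    inner_k: int = 5,
) -> tuple[np.ndarray, GAHistory]:
    """Run the GA wrapper and return (best chromosome, history).

    The chromosome ranges over ``candidate_features`` (default: all
    features); ``history.selected_indices`` maps the best chromosome back
    to original feature indices. ``performance_fn`` overrides the default
    inner cross-validated classifier Performance; it receives an array of
    original-space feature indices.
    """
    if performance_fn is None:
        if dataset is None or request is None:
            raise ValueError("need dataset and request (or a performance_fn)")
        inner_seed = (config.seed * 1000003 + 7919) % (2 ** 31)
        performance_fn = InnerCVEvaluator(dataset, request, k=inner_k,
                                          seed=inner_seed)
    if candidate_features is None:
        if dataset is None:
            raise ValueError("need dataset or explicit candidate_features")
        candidate_features = np.arange(dataset.n_features)
    candidates = np.asarray(sorted(set(map(int, candidate_features))), dtype=int)
    if candidates.size == 0:
        raise ValueError("candidate feature set is empty")
    m = candidates.size

    cache: dict[bytes, float] = {}
    history = GAHistory()

    def evaluate(pop: Population) -> None:
        keys = [member.tobytes() for member in pop.members]
        pending_keys, pending_bits = [], []
        seen = set()
        for key, member in zip(keys, pop.members):
            if key not in cache and key not in seen:
                seen.add(key)
                pending_keys.append(key)
                pending_bits.append(candidates[member.astype(bool)])
        results = _evaluate_pending(pending_bits, performance_fn,
                                    config.worker_count)
        history.n_evaluations += len(pending_bits)
        for key, perf in zip(pending_keys, results):
            cache[key] = perf
        pop.fitness = np.array([
            fitness(member, cache[key], config.alpha, m)
            for key, member in zip(keys, pop.members)])

    rng = np.random.default_rng(config.seed + 1)
    pop = initialize_population(m, config)
    evaluate(pop)
    best_i = _best_index(pop)
    best_bits = pop.members[best_i].copy()
    best_fit = float(pop.fitness[best_i])
    stagnant = 0

    def record(pop: Population) -> None:
        entry = {
            "generation": pop.generation,
            "best_fitness": best_fit,
            "mean_fitness": float(pop.fitness.mean()),
            "best_size": int(best_bits.sum()),
            "stagnation": stagnant,
        }
        history.generations.append(entry)
        logger.info("generation=%d best_fitness=%.6f best_size=%d stagnation=%d",
                    entry["generation"], entry["best_fitness"],
                    entry["best_size"], entry["stagnation"])

    record(pop)
    stop_reason = "max_generations"
    for gen in range(1, config.max_generations + 1):
        offspring: list[np.ndarray] = []
        while len(offspring) < config.population_size:
            p1, p2 = tournament_select(pop, rng)
            c1, c2 = two_point_crossover(p1, p2, rng, config.crossover_rate)
            offspring.append(mutate(c1, config.mutation_rate, rng))
            if len(offspring) < config.population_size:
                offspring.append(mutate(c2, config.mutation_rate, rng))
        # "best" population replacement: parents and offspring compete,
        # the best r survive (ties to smaller chromosomes, then parents)
        merged = Population(
            np.vstack([pop.members, np.asarray(offspring, dtype=np.uint8)]),
            None, gen)
        evaluate(merged)
        order = sorted(range(merged.members.shape[0]),
                       key=lambda i: (-merged.fitness[i],
                                      int(merged.members[i].sum()), i))
        keep = order[:config.population_size]
        pop = Population(merged.members[keep].copy(),
                         merged.fitness[keep].copy(), gen)
        gen_fit = float(pop.fitness[0])
        if gen_fit > best_fit:
            best_fit = gen_fit
            best_bits = pop.members[0].copy()
            stagnant = 0
        else:
            stagnant += 1
        record(pop)
        if stagnant >= config.stagnation_patience:
            stop_reason = "stagnation"
            break

    history.best_chromosome = best_bits
    history.selected_indices = [int(i) for i in candidates[best_bits.astype(bool)]]
    history.stop_reason = stop_reason
    return best_bits, history
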