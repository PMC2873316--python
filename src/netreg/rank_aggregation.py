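"""Weighted rank aggregation of regulator lists by genetic algorithm.

Combines several p-value-ranked lists into one ordered list of size k that
minimizes the summed weighted Spearman footrule distance to the inputs.
The optimizer is a steady generational GA with order-preserving crossover,
point mutation that swaps a member for an outside element, elitism of one,
and a convergence window; runs are reproducible given a seed.
"""

from __future__ import annotations

import dataclasses
import logging
from collections.abc import Sequence

import numpy as np

from .overconnectivity import RankedList

__all__ = [
    "GAConfig",
    "AggregationProblem",
    "weighted_spearman_distance",
    "aggregate",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass(frozen=True)
class GAConfig:
    population: int = 100
    generations: int = 500
    crossover_rate: float = 0.8
    mutation_rate: float = 0.05
    convergence_window: int = 50
    seed: int = 0


@dataclasses.dataclass
class AggregationProblem:
    """Two or more ranked input lists, a target size k, and GA settings."""

    input_lists: Sequence[RankedList]
    k: int = 20
    weight_scheme: str = "pvalue"  # or "uniform"
    ga: GAConfig = dataclasses.field(default_factory=GAConfig)

    def __post_init__(self) -> None:
        if len(self.input_lists) < 2:
            raise ValueError("need at least 2 input lists")
        if self.weight_scheme not in {"pvalue", "uniform"}:
            raise ValueError(f"unknown weight scheme {self.weight_scheme!r}")
        universe = self.universe()
        if self.k > len(universe):
            raise ValueError(
                f"k={self.k} exceeds the union of candidates ({len(universe)})"
            )
        if self.k < 1:
            raise ValueError("k must be >= 1")

    def universe(self) -> list[str]:
        seen: set[str] = set()
        for lst in self.input_lists:
            seen.update(lst.top(self.k).nodes)
        return sorted(seen)


def _position_weights(ref: RankedList, k: int, scheme: str) -> np.ndarray:
    """Importance of rank positions 1..k (position k+1, absent, gets 0).

    'pvalue': 1 minus the min-max-normalized p-value of the entry at that
    position (ties in p give equal weights).  'uniform': linearly
    decreasing (k, k-1, ..., 1), the plain Spearman footrule up to scale.
    """
    top = ref.top(k)
    if scheme == "uniform":
        return np.arange(k, 0, -1, dtype=float)
    p = np.asarray(top.p_values, dtype=float)
    if len(p) < k:
        raise ValueError(f"reference list shorter than k={k}")
    lo, hi = p.min(), p.max()
    if hi == lo:
        return np.arange(k, 0, -1, dtype=float)
    return 1.0 - (p - lo) / (hi - lo)


def weighted_spearman_distance(
    candidate: Sequence[str],
    ref: RankedList,
    k: int,
    weight_scheme: str = "pvalue",
) -> float:
    """Weighted Spearman footrule distance of a length-k ordered candidate.

    Over the union of the candidate and the reference's top-k, sums
    |W(rank in candidate) - W(rank in reference)| where W maps the
    reference's rank positions to importances and an element absent from a
    list sits at rank k+1 with importance 0.  Zero iff the candidate
    reproduces the reference's top-k in order.
    """
    candidate = list(candidate)
    if len(candidate) != k:
        raise ValueError(f"candidate must have length k={k}")
    if len(set(candidate)) != k:
        raise ValueError("duplicate element in candidate list")
    weights = _position_weights(ref, k, weight_scheme)
    ref_nodes = ref.top(k).nodes
    ref_rank = {node: i for i, node in enumerate(ref_nodes)}  # 0-based
    cand_rank = {node: i for i, node in enumerate(candidate)}

    def w(rank0: int | None) -> float:
        return 0.0 if rank0 is None else float(weights[rank0])

    total = 0.0
    for node in set(candidate) | set(ref_nodes):
        total += abs(w(cand_rank.get(node)) - w(ref_rank.get(node)))
    return total


def total_distance(candidate: Sequence[str], problem: AggregationProblem) -> float:
    """GA objective: summed distance to every input list."""
    return sum(
        weighted_spearman_distance(candidate, lst, problem.k, problem.weight_scheme)
        for lst in problem.input_lists
    )


def aggregate(problem: AggregationProblem) -> list[str]:
    """Return the ordered length-k list minimizing the total distance.

    Deterministic given ``problem.ga.seed`` and invariant to the order in
    which input lists are supplied.
    """
    k = problem.k
    universe = problem.universe()  # sorted -> list-order invariance
    cfg = problem.ga
    rng = np.random.default_rng(cfg.seed)

    # Seed individuals: each input list's top-k (canonical order), padded
    # from the universe when shorter; remainder random k-permutations.
    seeds: list[tuple[str, ...]] = []
    for lst in sorted(problem.input_lists, key=lambda L: tuple(L.top(k).nodes)):
        top = lst.top(k).nodes
        if len(top) < k:
            pad = [v for v in universe if v not in top]
            top = top + pad[: k - len(top)]
        seeds.append(tuple(top))
    population: list[tuple[str, ...]] = list(dict.fromkeys(seeds))
    while len(population) < cfg.population:
        perm = rng.permutation(len(universe))[:k]
        population.append(tuple(universe[i] for i in perm))

    def fitness(ind: tuple[str, ...]) -> float:
        return total_distance(ind, problem)

    scores = np.array([fitness(ind) for ind in population])
    best_idx = int(np.argmin(scores))
    best, best_score = population[best_idx], float(scores[best_idx])
    stall = 0

    for _gen in range(cfg.generations):
        order = np.argsort(scores, kind="stable")
        ranked = [population[i] for i in order]
        # rank-based selection probabilities
        sel_p = np.arange(len(ranked), 0, -1, dtype=float)
        sel_p /= sel_p.sum()

        next_pop: list[tuple[str, ...]] = [ranked[0]]  # elitism of 1
        while len(next_pop) < cfg.population:
            i, j = rng.choice(len(ranked), size=2, p=sel_p)
            a, b = ranked[int(i)], ranked[int(j)]
            if rng.random() < cfg.crossover_rate:
                child = _order_crossover(a, b, rng)
            else:
                child = a
            child = _mutate(child, universe, cfg.mutation_rate, rng)
            next_pop.append(child)

        population = next_pop
        scores = np.array([fitness(ind) for ind in population])
        gen_best = int(np.argmin(scores))
        if scores[gen_best] < best_score - 1e-12:
            best, best_score = population[gen_best], float(scores[gen_best])
            stall = 0
        else:
            stall += 1
            if stall >= cfg.convergence_window:
                break

    logger.debug("GA finished: best fitness %.6g", best_score)
    return list(best)


def _order_crossover(
    a: tuple[str, ...], b: tuple[str, ...], rng: np.random.Generator
) -> tuple[str, ...]:
    """One-point order-preserving crossover for permutation-like lists."""
    k = len(a)
    if k == 1:
        return a
    cut = int(rng.integers(1, k))
    head = list(a[:cut])
    tail = [x for x in b if x not in head]
    child = head + tail[: k - cut]
    # b may not contain enough novel elements when lists overlap partially
    if len(child) < k:
        child += [x for x in a if x not in child][: k - len(child)]
    return tuple(child)


def _mutate(
    ind: tuple[str, ...],
    universe: Sequence[str],
    rate: float,
    rng: np.random.Generator,
) -> tuple[str, ...]:
    """Point mutation: replace a member with an outside universe element.

    Falls back to swapping two positions when the universe has no outside
    elements (k == |universe|).
    """
    ind = list(ind)
    outside = [v for v in universe if v not in ind]
    for pos in range(len(ind)):
        if rng.random() < rate:
            if outside:
                j = int(rng.integers(len(outside)))
                ind[pos], outside[j] = outside[j], ind[pos]
            elif len(ind) > 1:
                j = int(rng.integers(len(ind)))
                ind[pos], ind[j] = ind[j], ind[pos]
    return tuple(ind)
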