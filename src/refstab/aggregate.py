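"""Consensus ranking by Spearman-footrule minimization.

Five method rankings rarely agree exactly; the consensus ordering is the
one minimizing the mean Spearman footrule distance (sum of absolute rank
displacements) to the input lists.  Two optimizers are provided: exhaustive
enumeration for small panels (the oracle) and a Cross-Entropy Monte-Carlo
search that maintains a gene x position sampling distribution, repeatedly
samples candidate orderings, and re-weights the distribution toward the
elite (lowest-objective) fraction.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

PROB_FLOOR = 1e-12


@dataclass
class RankedList:
    method: str
    genes: list[str]  # most stable first
    scores: list[float] | None = None  # optional, aligned with genes

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            raise ValueError("ranked list contains duplicate genes")
        if self.scores is not None and len(self.scores) != len(self.genes):
            raise ValueError("scores must align with genes")


@dataclass
class ConsensusRanking:
    genes: list[str]
    objective: float  # mean footrule distance to the input lists
    algorithm: str  # "cross_entropy" or "brute_force"
    iterations: int = 0
    seed: int | None = None
    converged: bool = True


def _check_same_universe(lists: list[RankedList]) -> list[str]:
    if not lists:
        raise ValueError("no ranked lists given")
    universe = sorted(lists[0].genes)
    for rl in lists[1:]:
        if sorted(rl.genes) != universe:
            raise ValueError("all ranked lists must cover the same gene set")
    return universe


def footrule_distance(a: list[str], b: list[str]) -> float:
    """Sum over genes of |position in a - position in b| (1-based ranks)."""
    if sorted(a) != sorted(b):
        raise ValueError("lists must be permutations of the same gene set")
    pos_b = {g: i for i, g in enumerate(b)}
    return float(sum(abs(i - pos_b[g]) for i, g in enumerate(a)))


def weighted_footrule_distance(a: RankedList, b: RankedList) -> float:
    """Footrule on min-max normalized stability scores instead of ranks."""
    if a.scores is None or b.scores is None:
        raise ValueError("weighted distance needs scores on both lists")

    def norm(rl: RankedList) -> dict[str, float]:
        s = np.asarray(rl.scores, dtype=float)
        rng = s.max() - s.min()
        z = (s - s.min()) / rng if rng > 0 else np.zeros_like(s)
        return dict(zip(rl.genes, z))

    na, nb = norm(a), norm(b)
    if sorted(na) != sorted(nb):
        raise ValueError("lists must cover the same gene set")
    return float(sum(abs(na[g] - nb[g]) for g in na))


def _positions(order: list[str], universe: list[str]) -> np.ndarray:
    pos = {g: i for i, g in enumerate(order)}
    return np.array([pos[g] for g in universe], dtype=float)


def mean_footrule_objective(order: list[str], lists: list[RankedList]) -> float:
    return float(np.mean([footrule_distance(order, rl.genes) for rl in lists]))


def aggregate_bruteforce(lists: list[RankedList]) -> ConsensusRanking:
    """Exhaustive search over all orderings; global optimum, n <= 8 only.

    Ties are resolved to the lexicographically smallest ordering.
    """
    universe = _check_same_universe(lists)
    n = len(universe)
    if n > 8:
        raise ValueError(
            f"brute force refuses n = {n} > 8 genes; use aggregate_ce instead"
        )
    # positions of each gene in each input list, aligned to sorted universe
    list_pos = np.stack([_positions(rl.genes, universe) for rl in lists])
    best_obj, best_perm = np.inf, None
    for perm in itertools.permutations(range(n)):  # lexicographic order
        pos = np.empty(n)
        pos[list(perm)] = np.arange(n)
        obj = np.abs(list_pos - pos).sum(axis=1).mean()
        if obj < best_obj - 1e-12:
            best_obj, best_perm = obj, perm
    genes = [universe[i] for i in best_perm]
    return ConsensusRanking(genes, float(best_obj), "brute_force")


def _sample_orderings(prob: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Sample ``size`` permutations: fill positions left to right, drawing a
    not-yet-used gene from the position's (renormalized) column."""
    n = prob.shape[0]
    orders = np.empty((size, n), dtype=np.int64)
    used = np.zeros((size, n), dtype=bool)
    for j in range(n):
        w = np.where(used, 0.0, prob[:, j][None, :].repeat(size, axis=0))
        w_sum = w.sum(axis=1, keepdims=True)
        flat = w_sum[:, 0] <= 0
        if flat.any():  # every allowed gene has zero mass: fall back to uniform
            w[flat] = (~used[flat]).astype(float)
            w_sum = w.sum(axis=1, keepdims=True)
        cum = np.cumsum(w / w_sum, axis=1)
        u = rng.random(size)
        pick = (u[:, None] > cum).sum(axis=1)
        pick = np.minimum(pick, n - 1)
        orders[:, j] = pick
        used[np.arange(size), pick] = True
    return orders


def aggregate_ce(
    lists: list[RankedList],
    sample_size: int = 500,
    rarity: float = 0.1,
    smoothing: float = 0.7,
    max_iter: int = 200,
    tol: float = 1e-8,
    seed: int | None = None,
    patience: int = 5,
) -> ConsensusRanking:
    """Cross-Entropy Monte-Carlo footrule minimization.

    Maintains an n x n probability matrix over (gene, position).  Each
    iteration samples ``sample_size`` orderings, keeps the ``rarity``
    quantile with the lowest objectives, and re-estimates the matrix as a
    smoothed mixture of the elite frequencies and the previous matrix.
    Stops when the elite objective has not improved for ``patience``
    iterations or at ``max_iter``.  The best-ever ordering is returned;
    deterministic given ``seed``.
    """
    if seed is None:
        raise ValueError("a seed is required for reproducible CE aggregation")
    if not 0.0 < rarity < 1.0:
        raise ValueError("rarity must lie in (0, 1)")
    if not 0.0 < smoothing <= 1.0:
        raise ValueError("smoothing must lie in (0, 1]")
    universe = _check_same_universe(lists)
    n = len(universe)
    if n < 2:
        raise ValueError("need at least 2 genes")
    rng = np.random.default_rng(seed)
    list_pos = np.stack([_positions(rl.genes, universe) for rl in lists])
    prob = np.full((n, n), 1.0 / n)
    n_elite = max(1, int(round(rarity * sample_size)))
    best_obj, best_order = np.inf, None
    elite_history: list[float] = []
    iterations = 0
    converged = False
    for it in range(1, max_iter + 1):
        iterations = it
        orders = _sample_orderings(prob, sample_size, rng)
        # objective: mean footrule to the input lists
        pos = np.empty_like(orders)
        np.put_along_axis(pos, orders, np.arange(n)[None, :].repeat(orders.shape[0], 0), axis=1)
        objs = np.abs(list_pos[None, :, :] - pos[:, None, :]).sum(axis=2).mean(axis=1)
        elite_idx = np.argsort(objs, kind="stable")[:n_elite]
        elite = orders[elite_idx]
        elite_best = float(objs[elite_idx[0]])
        if elite_best < best_obj - tol:
            best_obj = elite_best
            best_order = orders[elite_idx[0]].copy()
        # re-estimate: frequency of gene g at position j among the elite
        freq = np.zeros((n, n))
        for j in range(n):
            counts = np.bincount(elite[:, j], minlength=n)
            freq[:, j] = counts / elite.shape[0]
        prob = smoothing * freq + (1.0 - smoothing) * prob
        col_mass = prob.sum(axis=0)
        if (col_mass <= 0).any():
            warnings.warn("degenerate probability column; re-normalizing with floor", stacklevel=2)
        prob = np.maximum(prob, PROB_FLOOR)
        prob /= prob.sum(axis=0, keepdims=True)
        elite_history.append(elite_best)
        if len(elite_history) > patience and all(
            abs(h - best_obj) <= tol for h in elite_history[-patience:]
        ):
            converged = True
            break
    order = [universe[g] for g in best_order]  # best_order[j] = gene at position j
    return ConsensusRanking(
        order, float(best_obj), "cross_entropy", iterations, seed, converged
    )


def top_n(consensus: ConsensusRanking, n: int = 2) -> list[str]:
    """The recommended reference set: the n most stable consensus genes."""
    return consensus.genes[:n]
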