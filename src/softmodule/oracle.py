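"""Exact small-instance ground truth.

Everything the stochastic machinery estimates can, on small graphs, be
computed exactly by enumerating connected subgraphs: the posterior vertex
probabilities for a fixed or variable module order, and the optimal
connectivity-preserving ranking by exhaustive search.  These oracles back
the test suite and the toy-instance validation; they are never a runtime
substitute for the sampler.

Enumeration uses a bitmask variant of recursive extension with exclusion
(each connected induced subgraph of order k is produced exactly once, with
its minimum-index vertex as the enumeration root).  Posterior scores use
the cancelled forms — w_v**(a-1) for fixed order, (w_v/tau)**(a-1) for
variable order — and are normalised with log-sum-exp.

Also implemented here is the constructive reduction from Exact Cover by
3-Sets (X3C) to the optimal connectivity-preserving ranking problem, used
as a test fixture for the hardness boundary: instances with an exact cover
admit a CP ranking with objective sum_i i*p_i = 3/2, and no better.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

from .bum_model import clamp_weights
from .graph_core import InteractionGraph
from .ranking import Ranking, make_ranking

__all__ = [
    "X3CInstance",
    "DEFAULT_ENUMERATION_BUDGET",
    "EnumerationBudgetExceeded",
    "enumerate_connected_subgraphs",
    "exact_posterior_fixed",
    "exact_posterior_variable",
    "ranking_objective",
    "brute_force_ocpr",
    "build_x3c_reduction",
    "cover_ranking",
]

#: Safety cap on the number of enumerated subgraphs; oracle calls fail
#: fast instead of hanging on instances that are too large to enumerate.
DEFAULT_ENUMERATION_BUDGET = 50_000_000


class EnumerationBudgetExceeded(RuntimeError):
    pass


def _iter_masks(
    G: InteractionGraph, k: int, budget: int
) -> Iterator[tuple[int, int]]:
    """Yield ``(mask, count_so_far)`` for every connected induced
    k-subgraph, each exactly once, in deterministic order."""
    adj = G.adjacency_masks()
    n = G.n
    total = 0
    for root in range(n):
        allowed = -1 << (root + 1)  # indices strictly above the root
        s0 = 1 << root
        if k == 1:
            total += 1
            if total > budget:
                raise EnumerationBudgetExceeded(f"more than {budget} subgraphs")
            yield s0, total
            continue
        stack = [(s0, adj[root] & allowed, s0 | adj[root], 1)]
        while stack:
            s, ext, nbh, size = stack.pop()
            if size == k - 1:
                while ext:
                    w = ext & -ext
                    ext ^= w
                    total += 1
                    if total > budget:
                        raise EnumerationBudgetExceeded(
                            f"more than {budget} subgraphs"
                        )
                    yield s | w, total
                continue
            while ext:
                w = ext & -ext
                ext ^= w
                wi = w.bit_length() - 1
                stack.append(
                    (s | w, ext | (adj[wi] & allowed & ~nbh),
                     nbh | adj[wi] | w, size + 1)
                )


def _mask_to_ids(G: InteractionGraph, mask: int) -> frozenset[str]:
    ids = G.vertex_ids
    out = []
    while mask:
        b = mask & -mask
        mask ^= b
        out.append(ids[b.bit_length() - 1])
    return frozenset(out)


def enumerate_connected_subgraphs(
    G: InteractionGraph, k: int, budget: int = DEFAULT_ENUMERATION_BUDGET
) -> Iterator[frozenset[str]]:
    """Every connected induced subgraph of order exactly ``k``, once each."""
    if not (1 <= k <= G.n):
        raise ValueError(f"k must lie in [1, n], got {k}")
    for mask, _ in _iter_masks(G, k, budget):
        yield _mask_to_ids(G, mask)


def _mask_log_scores(
    G: InteractionGraph, k: int, per_vertex: Sequence[float], budget: int
) -> tuple[list[int], np.ndarray]:
    masks: list[int] = []
    scores: list[float] = []
    for mask, _ in _iter_masks(G, k, budget):
        m, acc = mask, 0.0
        while m:
            b = m & -m
            m ^= b
            acc += per_vertex[b.bit_length() - 1]
        masks.append(mask)
        scores.append(acc)
    return masks, np.array(scores)


def _marginalise(
    G: InteractionGraph, masks: Sequence[int], log_scores: np.ndarray
) -> np.ndarray:
    """Per-vertex posterior mass from subgraph log-scores (log-sum-exp)."""
    top = float(log_scores.max())
    weights = np.exp(log_scores - top)
    acc = np.zeros(G.n)
    for mask, wgt in zip(masks, weights):
        while mask:
            b = mask & -mask
            mask ^= b
            acc[b.bit_length() - 1] += wgt
    return acc / weights.sum()


def exact_posterior_fixed(
    G: InteractionGraph,
    weights: Mapping[str, float],
    a: float,
    k: int,
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> dict[str, float]:
    """Exact P(v in M | W = w) for a uniform prior over connected
    k-subgraphs and signal likelihood prod_{v in S} a * w_v**(a-1).

    The a**k factor is shared by all states and cancels; each subgraph's
    unnormalised log-score is (a-1) * sum_{v in S} log w_v.
    """
    w = clamp_weights(weights)
    per_vertex = [(a - 1.0) * math.log(w[v]) for v in G.vertex_ids]
    masks, scores = _mask_log_scores(G, k, per_vertex, budget)
    probs = _marginalise(G, masks, scores)
    return {v: float(probs[i]) for i, v in enumerate(G.vertex_ids)}


def exact_posterior_variable(
    G: InteractionGraph,
    weights: Mapping[str, float],
    a: float,
    tau: float,
    max_order: int,
    budget: int = DEFAULT_ENUMERATION_BUDGET,
) -> tuple[dict[str, float], dict[int, float]]:
    """Exact vertex marginals and order distribution for the
    variable-order stationary law pi(S) ~ prod_{v in S} (w_v/tau)**(a-1),
    truncated at ``max_order``.

    Returns ``(vertex_probabilities, P(|M| = m))``.
    """
    w = clamp_weights(weights)
    log_tau = math.log(tau)
    per_vertex = [(a - 1.0) * (math.log(w[v]) - log_tau) for v in G.vertex_ids]
    all_masks: list[int] = []
    all_scores: list[float] = []
    orders: list[int] = []
    used = 0
    for m in range(1, min(max_order, G.n) + 1):
        masks, scores = _mask_log_scores(G, m, per_vertex, budget - used)
        used += len(masks)
        all_masks.extend(masks)
        all_scores.extend(scores)
        orders.extend([m] * len(masks))
    scores_arr = np.array(all_scores)
    probs = _marginalise(G, all_masks, scores_arr)
    top = float(scores_arr.max())
    wgt = np.exp(scores_arr - top)
    wgt /= wgt.sum()
    orders_arr = np.array(orders)
    order_dist = {
        int(m): float(wgt[orders_arr == m].sum()) for m in np.unique(orders_arr)
    }
    return (
        {v: float(probs[i]) for i, v in enumerate(G.vertex_ids)},
        order_dist,
    )


def ranking_objective(ranking: Ranking | Sequence[str], p: Mapping[str, float]) -> float:
    """The CP-ranking objective sum over rank positions i of i * p_i.

    Minimising it is equivalent to maximising the expected AUC ROC."""
    order = ranking.order if isinstance(ranking, Ranking) else tuple(ranking)
    return sum(i * p[v] for i, v in enumerate(order, start=1))


def brute_force_ocpr(G: InteractionGraph, p: Mapping[str, float]) -> Ranking:
    """Optimal connectivity-preserving ranking by exhaustive search.

    Recursive prefix extension (a prefix may only grow by a vertex adjacent
    to it) with branch-and-bound on the partial objective.  Ties between
    optimal rankings go to the lexicographically smallest order sequence.
    Limited to n <= 10.
    """
    n = G.n
    if n > 10:
        raise ValueError("brute-force OCPR is limited to graphs with n <= 10")
    ids = G.vertex_ids
    pvals = [p[v] for v in ids]
    adj = G.adjacency_masks()
    best_obj = math.inf
    best_order: list[int] | None = None
    order: list[int] = []

    def rec(used_mask: int, reach_mask: int, depth: int, obj: float) -> None:
        nonlocal best_obj, best_order
        if obj > best_obj:
            return
        if depth == n:
            key = order.copy()
            if obj < best_obj or (obj == best_obj and (best_order is None or key < best_order)):
                best_obj = obj
                best_order = key
            return
        cand = reach_mask & ~used_mask if depth else (1 << n) - 1
        while cand:
            b = cand & -cand
            cand ^= b
            i = b.bit_length() - 1
            order.append(i)
            rec(used_mask | b, reach_mask | adj[i], depth + 1,
                obj + (depth + 1) * pvals[i])
            order.pop()

    rec(0, 0, 0, 0.0)
    assert best_order is not None
    return make_ranking([ids[i] for i in best_order], p, connectivity_preserving=True)


# ---------------------------------------------------------------------------
# X3C -> OCPR reduction fixture


@dataclass(frozen=True)
class X3CInstance:
    """An Exact Cover by 3-Sets instance: ground set X of 3q elements and
    a collection of 3-element subsets of X."""

    X: tuple[str, ...]
    C: tuple[frozenset[str], ...]

    @property
    def q(self) -> int:
        return len(self.X) // 3

    def __post_init__(self) -> None:
        if len(self.X) % 3 != 0 or not self.X:
            raise ValueError("|X| must be a positive multiple of 3")
        if len(set(self.X)) != len(self.X):
            raise ValueError("ground-set elements must be distinct")
        ground = set(self.X)
        for c in self.C:
            if len(c) != 3 or not c <= ground:
                raise ValueError(f"malformed triple {sorted(c)}")


def build_x3c_reduction(
    inst: X3CInstance,
) -> tuple[InteractionGraph, dict[str, float], float]:
    """Construct the OCPR instance encoding an X3C instance.

    The graph is a hub vertex ``v`` joined to one vertex per triple ``c_i``,
    each triple vertex joined to its three element vertices ``x_j``.
    Probabilities: p_v = 1, p_{c_i} = 0, p_{x_j} = eps = 1/(12q(q+1)).
    A CP ranking with objective sum i*p_i <= 3/2 exists iff the X3C
    instance has an exact cover; the bound 3/2 is returned.
    """
    covered = set().union(*inst.C) if inst.C else set()
    if covered != set(inst.X):
        raise ValueError("every ground-set element must occur in some triple "
                         "(otherwise the reduction graph is disconnected)")
    q = inst.q
    eps = 1.0 / (12 * q * (q + 1))
    adj: dict[str, set[str]] = {"v": set()}
    p: dict[str, float] = {"v": 1.0}
    elem_name = {x: f"x_{x}" for x in inst.X}
    for x in inst.X:
        adj[elem_name[x]] = set()
        p[elem_name[x]] = eps
    for i, triple in enumerate(inst.C, start=1):
        c = f"c{i}"
        adj[c] = {"v"}
        adj["v"].add(c)
        p[c] = 0.0
        for x in sorted(triple):
            adj[c].add(elem_name[x])
            adj[elem_name[x]].add(c)
    return InteractionGraph(adj), p, 1.5


def cover_ranking(inst: X3CInstance, cover_indices: Iterable[int]) -> list[str]:
    """The canonical CP ranking certified by an exact cover: the hub, then
    each cover triple followed by its three elements, then the remaining
    triple vertices.  Achieves objective exactly 3/2."""
    cover = list(cover_indices)
    order = ["v"]
    seen_elems: set[str] = set()
    for i in cover:
        triple = inst.C[i - 1]
        order.append(f"c{i}")
        for x in sorted(triple):
            if x in seen_elems:
                raise ValueError("given indices are not an exact cover")
            order.append(f"x_{x}")
            seen_elems.add(x)
    if seen_elems != set(inst.X):
        raise ValueError("given indices are not an exact cover")
    for i in range(1, len(inst.C) + 1):
        if i not in cover:
            order.append(f"c{i}")
    return order
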