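"""Vertex rankings and FDR-thresholded module extraction.

Three rankings are provided: descending membership probability (the
expected-AUC-optimal unconstrained order), ascending input p-value (the
baseline), and a connectivity-preserving order produced by a peeling
heuristic.  A connectivity-preserving (CP) ranking is one where every
prefix induces a connected subgraph, so thresholding the prefix FDR at any
level q yields a *nested* family of connected modules M(q).

Finding the CP ranking with maximal expected AUC is NP-hard, so the
heuristic peels the graph from the back: at each step it removes the
vertex whose removal splits off the vertex block with the highest average
FDR (mean of 1 - p), assigns that block the worst remaining ranks, and
recurses on the largest surviving component.  Each step costs O(n^2),
the whole ranking O(n^3).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .graph_core import InteractionGraph, is_connected_induced, split_by_removal

__all__ = [
    "Ranking",
    "make_ranking",
    "rank_by_probability",
    "rank_by_weight",
    "ocpr_heuristic",
    "module_at_fdr",
]


@dataclass(frozen=True)
class Ranking:
    """A total order on the graph vertices, rank 1 first.

    ``prefix_fdr[k-1]`` is the mean of (1 - p) over the first k vertices;
    it is only populated when probabilities were supplied.  When
    ``connectivity_preserving`` is set, every prefix induces a connected
    subgraph of the source graph.
    """

    order: tuple[str, ...]
    connectivity_preserving: bool = False
    prefix_fdr: tuple[float, ...] = ()

    def __len__(self) -> int:
        return len(self.order)

    def __iter__(self):
        return iter(self.order)


def make_ranking(
    order: Sequence[str],
    p: Mapping[str, float] | None = None,
    *,
    connectivity_preserving: bool = False,
) -> Ranking:
    prefix: tuple[float, ...] = ()
    if p is not None:
        acc = 0.0
        out = []
        for k, v in enumerate(order, start=1):
            acc += 1.0 - p[v]
            out.append(acc / k)
        prefix = tuple(out)
    return Ranking(tuple(order), connectivity_preserving, prefix)


def rank_by_probability(
    p: Mapping[str, float], w: Mapping[str, float] | None = None
) -> Ranking:
    """Rank by descending membership probability.

    Ties are broken by ascending input p-value (when given), then by
    vertex id.  By the closed-form expected AUC this order is optimal
    among all (unconstrained) rankings.
    """
    if w is None:
        key = lambda v: (-p[v], v)  # noqa: E731
    else:
        key = lambda v: (-p[v], w[v], v)  # noqa: E731
    order = sorted(p, key=key)
    return make_ranking(order, p)


def rank_by_weight(w: Mapping[str, float]) -> Ranking:
    """Baseline: rank by ascending input p-value, ties by vertex id."""
    order = sorted(w, key=lambda v: (w[v], v))
    return make_ranking(order)


def ocpr_heuristic(G: InteractionGraph, p: Mapping[str, float]) -> Ranking:
    """Connectivity-preserving ranking by iterative peeling.

    At step k (current connected subgraph ``G_k``, worst unassigned rank
    ``r_k``), every vertex v is scored by splitting ``G_k`` at v into the
    largest surviving component ``G^(v)`` and the peeled block
    ``H = G_k \\ G^(v)`` (v included); the v maximising the average FDR
    mean(1 - p) over H wins (ties: smaller |H|, then smaller id).  H takes
    ranks r_k - |H| + 1 .. r_k and the algorithm recurses on ``G^(v)``
    until a single vertex remains at rank 1.

    Within a block the ranks are ordered greedily so that every global
    prefix stays connected: repeatedly place earliest the highest-p block
    vertex adjacent to the surviving component or to an already placed
    block vertex.
    """
    missing = [v for v in G.vertex_ids if v not in p]
    if missing:
        raise ValueError(f"probabilities missing for {missing[:5]}")
    current = G
    blocks: list[list[str]] = []
    while current.n > 1:
        best = None
        for v in current.vertex_ids:
            g_next, h = split_by_removal(current, v)
            fdr = sum(1.0 - p[u] for u in h) / len(h)
            key = (-fdr, len(h), v)
            if best is None or key < best[0]:
                best = (key, v, g_next, h)
        _, v, g_next, h = best
        blocks.append(_order_block(G, g_next, h, p))
        current = current.induced_subgraph(g_next)
    order = [current.vertex_ids[0]]
    for block in reversed(blocks):
        order.extend(block)
    ranking = make_ranking(order, p, connectivity_preserving=True)
    _assert_cp(G, ranking.order)
    return ranking


def _order_block(
    G: InteractionGraph,
    base: frozenset[str],
    block: frozenset[str],
    p: Mapping[str, float],
) -> list[str]:
    """Order a peeled block so every global prefix stays connected.

    Eligible vertices are those adjacent (in G) to the surviving component
    ``base`` or to an already placed block vertex; among them the one with
    the highest p (ties: smaller id) is placed earliest.
    """
    placed: list[str] = []
    anchor = set(base)
    remaining = set(block)
    while remaining:
        eligible = [u for u in remaining if G.adjacency[u] & anchor]
        if not eligible and not anchor:
            eligible = list(remaining)  # degenerate: block is the whole graph
        u = min(eligible, key=lambda x: (-p[x], x))
        placed.append(u)
        anchor.add(u)
        remaining.remove(u)
    return placed


def _assert_cp(G: InteractionGraph, order: Sequence[str]) -> None:
    seen: set[str] = set()
    for i, v in enumerate(order):
        if i > 0 and not (G.adjacency[v] & seen):
            raise AssertionError(
                f"ranking is not connectivity preserving at position {i + 1}"
            )
        seen.add(v)


def module_at_fdr(
    ranking: Ranking, p: Mapping[str, float], q: float
) -> frozenset[str]:
    """Longest ranking prefix whose average FDR is at most ``q``.

    Requires a connectivity-preserving ranking so the returned vertex sets
    are connected and nested across FDR levels.  Returns the empty set
    when even the top vertex exceeds ``q``.
    """
    if not ranking.connectivity_preserving:
        raise ValueError("module extraction requires a connectivity-preserving ranking")
    if not (0.0 <= q <= 1.0):
        raise ValueError("FDR level q must lie in [0, 1]")
    acc = 0.0
    best = 0
    for k, v in enumerate(ranking.order, start=1):
        acc += 1.0 - p[v]
        if acc / k <= q:
            best = k
    return frozenset(ranking.order[:best])
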