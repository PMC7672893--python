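"""Undirected interaction-graph container and connectivity primitives.

The global network is a simple, undirected, connected graph whose vertices
are opaque string identifiers (typically gene or protein symbols).  All
other modules operate on :class:`InteractionGraph` or on plain vertex-id
sets drawn from it.  Tie-breaking anywhere in the package falls back to
lexicographic order on vertex ids, which makes every algorithm
deterministic given a seed.
"""

from __future__ import annotations

import logging
from collections import deque
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

__all__ = [
    "InteractionGraph",
    "load_graph",
    "read_edgelist_tsv",
    "read_graphml",
    "neighborhood",
    "is_connected_induced",
    "split_by_removal",
]


class InteractionGraph:
    """A simple undirected connected graph with string vertex ids.

    Vertices are stored in sorted order; ``vertex_ids[i]`` is the vertex
    with internal index ``i``.  Hot loops (the MCMC sampler, the exact
    enumerator) work on the integer indices and on the per-vertex adjacency
    bitmasks exposed here; user-facing functions speak vertex ids.
    """

    __slots__ = ("vertex_ids", "_index", "_adj_idx", "_adj_mask", "adjacency", "n")

    def __init__(self, adjacency: Mapping[str, Iterable[str]]):
        ids = sorted(adjacency)
        self.vertex_ids: tuple[str, ...] = tuple(ids)
        self.n: int = len(ids)
        self._index: dict[str, int] = {v: i for i, v in enumerate(ids)}
        adj: dict[str, frozenset[str]] = {}
        for v, nbrs in adjacency.items():
            adj[v] = frozenset(nbrs)
        # symmetry / simplicity checks
        for v, nbrs in adj.items():
            if v in nbrs:
                raise ValueError(f"self-loop at vertex {v!r}")
            for u in nbrs:
                if u not in adj or v not in adj[u]:
                    raise ValueError(f"asymmetric adjacency between {v!r} and {u!r}")
        self.adjacency: dict[str, frozenset[str]] = adj
        idx = self._index
        self._adj_idx: list[list[int]] = [
            sorted(idx[u] for u in adj[v]) for v in ids
        ]
        masks = []
        for nbrs in self._adj_idx:
            m = 0
            for j in nbrs:
                m |= 1 << j
            masks.append(m)
        self._adj_mask: list[int] = masks
        if self.n == 0:
            raise ValueError("empty graph")
        if not self._is_connected_all():
            raise ValueError("graph is not connected")

    # -- basic queries -------------------------------------------------

    def index(self, v: str) -> int:
        return self._index[v]

    def neighbors(self, v: str) -> frozenset[str]:
        return self.adjacency[v]

    def neighbor_indices(self, i: int) -> list[int]:
        return self._adj_idx[i]

    def adjacency_masks(self) -> list[int]:
        """Per-vertex neighbor bitmasks (bit j set iff vertex j adjacent)."""
        return self._adj_mask

    def has_edge(self, u: str, v: str) -> bool:
        return v in self.adjacency[u]

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.adjacency.values()) // 2

    def edges(self) -> list[tuple[str, str]]:
        out = []
        for v in self.vertex_ids:
            for u in self.adjacency[v]:
                if v < u:
                    out.append((v, u))
        return out

    def __contains__(self, v: str) -> bool:
        return v in self._index

    def __len__(self) -> int:
        return self.n

    def __repr__(self) -> str:  # pragma: no cover
        return f"InteractionGraph(n={self.n}, m={self.n_edges})"

    def _is_connected_all(self) -> bool:
        if self.n == 0:
            return False
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in self._adj_idx[i]:
                if j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == self.n

    # -- derived graphs ------------------------------------------------

    def induced_subgraph(self, members: Iterable[str]) -> "InteractionGraph":
        """Induced subgraph on ``members`` (must itself be connected)."""
        mset = set(members)
        missing = mset - set(self._index)
        if missing:
            raise KeyError(f"vertices not in graph: {sorted(missing)[:5]}")
        return InteractionGraph({v: self.adjacency[v] & mset for v in mset})

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.vertex_ids)
        g.add_edges_from(self.edges())
        return g


def load_graph(edges: Sequence[tuple[str, str]]) -> InteractionGraph:
    """Build an :class:`InteractionGraph` from an edge list.

    Self-loops and duplicate edges are dropped silently.  If the resulting
    simple graph is disconnected, only the largest connected component is
    kept (ties broken toward the component holding the lexicographically
    smallest vertex id) and a warning reports how many vertices were
    discarded.
    """
    if not edges:
        raise ValueError("empty edge list")
    adj: dict[str, set[str]] = {}
    for u, v in edges:
        u, v = str(u), str(v)
        if u == v:
            continue
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    if not adj:
        raise ValueError("edge list contains only self-loops")
    comps = _components(adj)
    comps.sort(key=lambda c: (-len(c), min(c)))
    keep = comps[0]
    dropped = sum(len(c) for c in comps[1:])
    if dropped:
        logger.warning(
            "input graph is disconnected: keeping largest component "
            "(%d vertices), discarding %d vertices", len(keep), dropped,
        )
    return InteractionGraph({v: adj[v] & keep for v in keep})


def read_edgelist_tsv(path) -> InteractionGraph:
    """Read a two-column tab-separated edge list.

    A header line is detected and skipped when neither of its two fields
    reappears as an endpoint anywhere later in the file.
    """
    rows: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 2 tab-separated columns")
            rows.append((parts[0].strip(), parts[1].strip()))
    if not rows:
        raise ValueError(f"{path}: no edges")
    if len(rows) > 1:
        endpoints = {x for r in rows[1:] for x in r}
        if rows[0][0] not in endpoints and rows[0][1] not in endpoints:
            rows = rows[1:]  # header
    return load_graph(rows)


def read_graphml(path) -> InteractionGraph:
    g = nx.read_graphml(path)
    return load_graph([(str(u), str(v)) for u, v in g.edges()])


def neighborhood(G: InteractionGraph, S: Iterable[str]) -> set[str]:
    """Vertices at distance exactly 1 from the vertex set ``S`` (nei(S))."""
    sset = set(S)
    out: set[str] = set()
    for v in sset:
        out |= G.adjacency[v]
    return out - sset


def is_connected_induced(G: InteractionGraph, S: Iterable[str]) -> bool:
    """True iff the subgraph induced on ``S`` has one connected component."""
    sset = set(S)
    if not sset:
        raise ValueError("empty vertex set")
    start = next(iter(sset))
    seen = {start}
    queue = deque([start])
    while queue:
        v = queue.popleft()
        for u in G.adjacency[v]:
            if u in sset and u not in seen:
                seen.add(u)
                queue.append(u)
    return len(seen) == len(sset)


def split_by_removal(
    G_k: InteractionGraph, v: str
) -> tuple[frozenset[str], frozenset[str]]:
    """Remove ``v`` from the connected graph ``G_k`` and split the vertices.

    Returns ``(G_next, H)`` where ``G_next`` is the vertex set of the
    largest connected component of ``G_k`` minus ``v`` (ties broken toward
    the component containing the lexicographically smallest id) and
    ``H`` is everything else, including ``v`` itself.
    """
    if v not in G_k:
        raise KeyError(v)
    rest = {u: G_k.adjacency[u] - {v} for u in G_k.vertex_ids if u != v}
    if not rest:
        return frozenset(), frozenset({v})
    comps = _components(rest)
    comps.sort(key=lambda c: (-len(c), min(c)))
    g_next = frozenset(comps[0])
    h = frozenset(G_k.vertex_ids) - g_next
    return g_next, h


def _components(adj: Mapping[str, set[str] | frozenset[str]]) -> list[set[str]]:
    seen: set[str] = set()
    comps: list[set[str]] = []
    for start in adj:
        if start in seen:
            continue
        comp = {start}
        stack = [start]
        while stack:
            x = stack.pop()
            for y in adj[x]:
                if y not in comp:
                    comp.add(y)
                    stack.append(y)
        seen |= comp
        comps.append(comp)
    return comps
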