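"""Metropolis-Hastings sampling of connected subgraphs.

Two chains over the connected subgraphs of the interaction graph:

* **fixed order** — the state is a connected subgraph of constant order k.
  A step swaps one member ``v-`` (uniform over the state S) for one
  frontier vertex ``v+`` (uniform over nei(S), computed *before* the
  removal), giving proposal probability Q(S'|S) = 1 / (|nei(S)| * |S|).
  With the signal likelihood L(S) = prod_{v in S} a * w_v**(a-1) and a
  uniform prior over connected k-subgraphs, the acceptance probability is

      rho = min{1, (w_+ / w_-)**(a-1) * |nei(S)| / |nei(S')|},

  and rho = 0 whenever the swap disconnects the subgraph.

* **variable order** — the state is any non-empty connected subgraph.  One
  vertex is drawn uniformly from the closed neighbourhood nei(S) + V(S):
  a frontier pick proposes an addition, a member pick a removal.  Each
  extra vertex is penalised by the prior factor a * tau**(a-1) (tau is a
  confidence threshold on p-values), which makes the stationary law
  proportional to prod_{v in S} (w_v / tau)**(a-1).

Per-vertex membership probabilities are estimated as occurrence
frequencies over the collected sample set.
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .graph_core import InteractionGraph, neighborhood
from .bum_model import clamp_weights

logger = logging.getLogger(__name__)

__all__ = [
    "ChainConfig",
    "ModuleState",
    "SampleCollection",
    "init_state",
    "propose_fixed",
    "acceptance_fixed",
    "acceptance_variable",
    "run_chain",
    "estimate_vertex_probabilities",
]


class _IndexedSet:
    """Set of small ints with O(1) add/discard/uniform-choice."""

    __slots__ = ("_items", "_pos")

    def __init__(self, items: Iterable[int] = ()):  # noqa: D107
        self._items: list[int] = []
        self._pos: dict[int, int] = {}
        for x in items:
            self.add(x)

    def add(self, x: int) -> None:
        if x not in self._pos:
            self._pos[x] = len(self._items)
            self._items.append(x)

    def discard(self, x: int) -> None:
        i = self._pos.pop(x, None)
        if i is None:
            return
        last = self._items.pop()
        if last != x:
            self._items[i] = last
            self._pos[last] = i

    def choose(self, rng: random.Random) -> int:
        return self._items[rng.randrange(len(self._items))]

    def __contains__(self, x: int) -> bool:
        return x in self._pos

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)


class ModuleState:
    """A connected candidate module with incrementally maintained frontier.

    Internally index-based.  ``cnt[u]`` counts the neighbours of ``u``
    inside the state; the frontier is exactly the set of non-members with
    ``cnt > 0``, so both are updated in O(deg) per vertex move.
    """

    def __init__(self, G: InteractionGraph, members_idx: Iterable[int], a: float,
                 logw: Sequence[float]):
        self.G = G
        self.a = a
        self._logw = logw
        self.members = _IndexedSet()
        self.frontier = _IndexedSet()
        self.cnt = [0] * G.n
        self.sum_logw = 0.0
        for i in members_idx:
            self.add(i)

    # -- mutation ------------------------------------------------------

    def add(self, i: int) -> None:
        self.members.add(i)
        self.frontier.discard(i)
        self.sum_logw += self._logw[i]
        cnt = self.cnt
        members = self.members
        frontier = self.frontier
        for j in self.G.neighbor_indices(i):
            cnt[j] += 1
            if j not in members:
                frontier.add(j)

    def remove(self, i: int) -> None:
        self.members.discard(i)
        self.sum_logw -= self._logw[i]
        cnt = self.cnt
        members = self.members
        frontier = self.frontier
        for j in self.G.neighbor_indices(i):
            cnt[j] -= 1
            if cnt[j] == 0 and j not in members:
                frontier.discard(j)
        if cnt[i] > 0:
            frontier.add(i)

    # -- queries -------------------------------------------------------

    def is_connected(self) -> bool:
        members = self.members
        k = len(members)
        if k == 0:
            return False
        start = members._items[0]
        seen = {start}
        stack = [start]
        adj = self.G._adj_idx
        while stack:
            v = stack.pop()
            for u in adj[v]:
                if u in members and u not in seen:
                    seen.add(u)
                    if len(seen) == k:
                        return True
                    stack.append(u)
        return len(seen) == k

    @property
    def order(self) -> int:
        return len(self.members)

    @property
    def log_likelihood(self) -> float:
        """log L(S) = |S| * log a + (a - 1) * sum_{v in S} log w_v."""
        return self.order * math.log(self.a) + (self.a - 1.0) * self.sum_logw

    def member_ids(self) -> frozenset[str]:
        ids = self.G.vertex_ids
        return frozenset(ids[i] for i in self.members)

    def frontier_ids(self) -> frozenset[str]:
        ids = self.G.vertex_ids
        return frozenset(ids[i] for i in self.frontier)


@dataclass
class ChainConfig:
    """Settings of one MCMC run.

    ``mode`` selects the fixed-order chain (requires ``k``) or the
    variable-order chain (requires ``tau``); ``a`` is the beta shape of the
    signal component.  ``strategy`` chooses between one long run, where
    every post-burn-in state (including repeats after rejection) is a
    sample, and ``independent_runs``, where ``n_runs`` chains each
    contribute only their final state.
    """

    mode: Literal["fixed_order", "variable_order"]
    a: float
    n_iterations: int
    k: int | None = None
    tau: float | None = None
    burn_in: int = 25_000
    strategy: Literal["one_long_run", "independent_runs"] = "one_long_run"
    n_runs: int = 1
    seed: int = 0
    trace_every: int = 1000
    retain_samples: bool = False

    def __post_init__(self) -> None:
        if self.mode == "fixed_order":
            if self.k is None or self.k < 1:
                raise ValueError("fixed_order mode requires k >= 1")
        elif self.mode == "variable_order":
            if self.tau is None or not (0.0 < self.tau < 1.0):
                raise ValueError("variable_order mode requires tau in (0,1)")
        else:
            raise ValueError(f"unknown mode {self.mode!r}")
        if not (0.0 < self.a <= 1.0):
            raise ValueError("a must be in (0,1]")
        if self.strategy == "one_long_run" and self.burn_in >= self.n_iterations:
            raise ValueError("burn_in must be smaller than n_iterations")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be positive")


@dataclass
class SampleCollection:
    """The sample set of subgraphs with its sufficient statistics.

    Per-vertex occurrence counts, per-order tallies and joint
    (vertex, order) counts are always kept; the raw subgraphs themselves
    are kept only when the chain ran with ``retain_samples`` (needed for
    arbitrary boolean event queries).
    """

    graph: InteractionGraph
    n_samples: int = 0
    vertex_counts: dict[str, int] = field(default_factory=dict)
    size_counts: dict[int, int] = field(default_factory=dict)
    vertex_size_counts: dict[tuple[str, int], int] = field(default_factory=dict)
    retained_samples: list[frozenset[str]] | None = None
    trace: list[tuple[int, float]] = field(default_factory=list)

    def check(self) -> None:
        assert sum(self.size_counts.values()) == self.n_samples
        for v in self.graph.vertex_ids:
            total = sum(
                c for (u, _m), c in self.vertex_size_counts.items() if u == v
            )
            assert total == self.vertex_counts.get(v, 0)


def init_state(
    G: InteractionGraph,
    mode: str,
    k: int | None,
    seed_or_rng: int | random.Random,
    *,
    a: float = 1.0,
    weights: Mapping[str, float] | None = None,
) -> ModuleState:
    """Random initial state: a seeded connected growth.

    Fixed mode starts from a uniform random vertex and repeatedly adds a
    uniform random frontier vertex until order ``k``; variable mode starts
    from a single uniform random vertex.  The growth law is *not* uniform
    over connected k-subgraphs — ergodicity of the chain makes the start
    irrelevant after burn-in.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, random.Random) else random.Random(seed_or_rng)
    logw = _log_weights(G, weights)
    if mode == "variable_order":
        k = 1
    if k is None or not (1 <= k <= G.n):
        raise ValueError(f"module order k must satisfy 1 <= k <= n, got {k}")
    state = ModuleState(G, [rng.randrange(G.n)], a, logw)
    while state.order < k:
        state.add(state.frontier.choose(rng))
    return state


def _log_weights(G: InteractionGraph, weights: Mapping[str, float] | None) -> list[float]:
    if weights is None:
        return [0.0] * G.n
    w = clamp_weights(weights)
    missing = [v for v in G.vertex_ids if v not in w]
    if missing:
        raise ValueError(f"unweighted vertices: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    return [math.log(w[v]) for v in G.vertex_ids]


def propose_fixed(
    G: InteractionGraph, S: ModuleState, rng: random.Random
) -> tuple[frozenset[str], str, str, float]:
    """One fixed-order proposal: swap a member for a frontier vertex.

    Returns ``(S', v_minus, v_plus, q_forward)`` where
    ``q_forward = 1 / (|nei(S)| * |S|)``.  ``S'`` may be disconnected; the
    caller rejects such proposals through a zero acceptance probability.
    """
    if len(S.frontier) == 0:
        raise ValueError("state has empty neighborhood; is k = n?")
    v_minus = S.members.choose(rng)
    v_plus = S.frontier.choose(rng)
    q_forward = 1.0 / (len(S.frontier) * len(S.members))
    ids = G.vertex_ids
    new = set(ids[i] for i in S.members)
    new.discard(ids[v_minus])
    new.add(ids[v_plus])
    return frozenset(new), ids[v_minus], ids[v_plus], q_forward


def acceptance_fixed(
    G: InteractionGraph,
    weights: Mapping[str, float],
    a: float,
    S: Iterable[str],
    S_prime: Iterable[str],
    v_minus: str,
    v_plus: str,
) -> float:
    """Acceptance probability of a fixed-order swap (id-level reference).

    rho = min{1, (w_+**(a-1) / w_-**(a-1)) * |nei(S)| / |nei(S')|}, and 0
    when S' is disconnected.  The run loop uses an equivalent incremental
    log-space computation; this function is the plain specification of it.
    """
    from .graph_core import is_connected_induced

    s_prime = set(S_prime)
    if not is_connected_induced(G, s_prime):
        return 0.0
    w = clamp_weights(weights)
    log_ratio = (a - 1.0) * (math.log(w[v_plus]) - math.log(w[v_minus]))
    log_ratio += math.log(len(neighborhood(G, S))) - math.log(len(neighborhood(G, s_prime)))
    return min(1.0, math.exp(log_ratio))


def acceptance_variable(
    G: InteractionGraph,
    weights: Mapping[str, float],
    a: float,
    tau: float,
    S: Iterable[str],
    S_prime: Iterable[str],
) -> float:
    """Acceptance probability of a variable-order addition or removal.

    Addition of v+:  rho = min{1, (w_+ / tau)**(a-1) * |nei(S)+V(S)| / |nei(S')+V(S')|}
    Removal of v-:   rho = min{1, (tau / w_-)**(a-1) * |nei(S)+V(S)| / |nei(S')+V(S')|}

    and 0 when the removal disconnects the subgraph.
    """
    from .graph_core import is_connected_induced

    s = set(S)
    s_prime = set(S_prime)
    w = clamp_weights(weights)
    closed = len(s | neighborhood(G, s))
    if len(s_prime) == len(s) + 1:
        (v_plus,) = s_prime - s
        log_ratio = (a - 1.0) * (math.log(w[v_plus]) - math.log(tau))
    elif len(s_prime) == len(s) - 1 and len(s_prime) >= 1:
        (v_minus,) = s - s_prime
        if not is_connected_induced(G, s_prime):
            return 0.0
        log_ratio = (a - 1.0) * (math.log(tau) - math.log(w[v_minus]))
    else:
        raise ValueError("S' must differ from S by exactly one vertex")
    closed_prime = len(s_prime | neighborhood(G, s_prime))
    log_ratio += math.log(closed) - math.log(closed_prime)
    return min(1.0, math.exp(log_ratio))


def run_chain(
    G: InteractionGraph,
    weights: Mapping[str, float] | None,
    config: ChainConfig,
) -> SampleCollection:
    """Run the configured chain and collect samples.

    ``one_long_run``: every visited state after the burn-in contributes a
    sample, *including* repeats after rejected proposals — occupancy times
    are what estimate the stationary law.  ``independent_runs``: each of
    ``n_runs`` chains contributes only its final state.  The subgraph
    log-likelihood is recorded every ``trace_every`` iterations.  Fully
    deterministic given ``config.seed``.
    """
    if config.mode == "fixed_order" and config.k is not None and config.k >= G.n:
        raise ValueError("k must be smaller than the graph order")
    logw = _log_weights(G, weights)
    coll = SampleCollection(graph=G)
    if config.retain_samples:
        coll.retained_samples = []
    vcounts = np.zeros(G.n, dtype=np.int64)
    vscounts: dict[int, np.ndarray] = {}

    if config.strategy == "one_long_run":
        rng = random.Random(config.seed)
        state = init_state(G, config.mode, config.k, rng, a=config.a, weights=weights)
        _iterate(state, config, rng, logw, coll, vcounts, vscounts,
                 collect_from=config.burn_in, record_trace=True)
    elif config.strategy == "independent_runs":
        ss = np.random.SeedSequence(config.seed)
        for child in ss.spawn(config.n_runs):
            rng = random.Random(int(child.generate_state(1, np.uint32)[0]))
            state = init_state(G, config.mode, config.k, rng, a=config.a, weights=weights)
            _iterate(state, config, rng, logw, coll, vcounts, vscounts,
                     collect_from=None, record_trace=False)
            _record(state, coll, vcounts, vscounts)
    else:
        raise ValueError(f"unknown strategy {config.strategy!r}")

    ids = G.vertex_ids
    coll.vertex_counts = {ids[i]: int(c) for i, c in enumerate(vcounts) if c}
    coll.size_counts = {m: int(sz) for m, sz in sorted(_size_totals(vscounts).items())}
    coll.vertex_size_counts = {
        (ids[i], m): int(arr[i])
        for m, arr in sorted(vscounts.items())
        for i in np.nonzero(arr)[0]
    }
    return coll


def _size_totals(vscounts: dict[int, np.ndarray]) -> dict[int, int]:
    # each sample of order m contributes m vertex-occurrences at that order
    return {m: int(arr.sum()) // m for m, arr in vscounts.items() if arr.sum()}


def _record(state: ModuleState, coll: SampleCollection,
            vcounts: np.ndarray, vscounts: dict[int, np.ndarray]) -> None:
    m = state.order
    arr = vscounts.get(m)
    if arr is None:
        arr = vscounts[m] = np.zeros(state.G.n, dtype=np.int64)
    for i in state.members:
        vcounts[i] += 1
        arr[i] += 1
    coll.n_samples += 1
    if coll.retained_samples is not None:
        coll.retained_samples.append(state.member_ids())


def _iterate(
    state: ModuleState,
    config: ChainConfig,
    rng: random.Random,
    logw: Sequence[float],
    coll: SampleCollection,
    vcounts: np.ndarray,
    vscounts: dict[int, np.ndarray],
    collect_from: int | None,
    record_trace: bool,
) -> None:
    """Advance the chain ``config.n_iterations`` steps (hot loop)."""
    a1 = config.a - 1.0
    mode_fixed = config.mode == "fixed_order"
    log_tau = math.log(config.tau) if config.tau is not None else 0.0
    members = state.members
    frontier = state.frontier
    for it in range(1, config.n_iterations + 1):
        if mode_fixed:
            v_minus = members.choose(rng)
            v_plus = frontier.choose(rng)
            old_nei = len(frontier)
            state.remove(v_minus)
            state.add(v_plus)
            if not state.is_connected():
                state.remove(v_plus)
                state.add(v_minus)
            else:
                log_rho = (a1 * (logw[v_plus] - logw[v_minus])
                           + math.log(old_nei) - math.log(len(frontier)))
                if log_rho < 0.0 and rng.random() >= math.exp(log_rho):
                    state.remove(v_plus)
                    state.add(v_minus)
        else:
            closed = len(members) + len(frontier)
            j = rng.randrange(closed)
            if j >= len(members):
                # addition of a frontier vertex
                v_plus = frontier._items[j - len(members)]
                state.add(v_plus)
                log_rho = (a1 * (logw[v_plus] - log_tau)
                           + math.log(closed) - math.log(len(members) + len(frontier)))
                if log_rho < 0.0 and rng.random() >= math.exp(log_rho):
                    state.remove(v_plus)
            else:
                v_minus = members._items[j]
                if len(members) == 1:
                    pass  # empty module is not a state: reject, state repeats
                else:
                    state.remove(v_minus)
                    if not state.is_connected():
                        state.add(v_minus)
                    else:
                        log_rho = (a1 * (log_tau - logw[v_minus])
                                   + math.log(closed)
                                   - math.log(len(members) + len(frontier)))
                        if log_rho < 0.0 and rng.random() >= math.exp(log_rho):
                            state.add(v_minus)
        if collect_from is not None and it > collect_from:
            _record(state, coll, vcounts, vscounts)
        if record_trace and it % config.trace_every == 0:
            coll.trace.append((it, state.log_likelihood))


def estimate_vertex_probabilities(samples: SampleCollection) -> dict[str, float]:
    """Occurrence frequency of every graph vertex over the sample set."""
    if samples.n_samples < 1:
        raise ValueError("empty sample collection")
    n = samples.n_samples
    return {
        v: samples.vertex_counts.get(v, 0) / n for v in samples.graph.vertex_ids
    }
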