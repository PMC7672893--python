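"""Simulation-instance generator.

An instance consists of a random connected graph, a planted connected
module chosen uniformly at random among the connected subgraphs of its
order, and per-vertex weights: beta(a, 1)-distributed p-values on the
module, Uniform(0, 1) elsewhere.  Default study conditions: the module
order is drawn uniformly from 5%..25% of the graph order and the beta
shape ``a`` from [0.01, 0.5]; benchmark graphs are scale-free
(preferential attachment), with Erdos-Renyi available as an alternative.

Uniformity of the planted module is obtained by running the fixed-order
chain with constant weights (the a = 1 case), whose stationary law is
uniform over connected subgraphs of the given order; rejection sampling
would be hopeless at realistic module sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np

from .graph_core import InteractionGraph, load_graph
from .sampler import ChainConfig, init_state, run_chain
import math
import random

__all__ = [
    "SyntheticInstance",
    "random_connected_graph",
    "sample_uniform_module",
    "generate_weights",
    "generate_instance",
    "toy_instance",
]

_MAX_GNP_ATTEMPTS = 1000


@dataclass(frozen=True)
class SyntheticInstance:
    """A generated benchmark instance with full provenance."""

    graph: InteractionGraph
    module: frozenset[str]
    weights: dict[str, float]
    gen_params: dict = field(default_factory=dict)


def _vertex_name(i: int, n: int) -> str:
    width = len(str(n - 1))
    return f"g{i:0{width}d}"


def random_connected_graph(
    n: int,
    model: Literal["erdos_renyi", "scale_free"],
    param: float,
    seed: int,
) -> InteractionGraph:
    """Random connected graph with string vertex ids g000, g001, ...

    ``erdos_renyi``: G(n, p) with edge probability ``param``, resampled
    until connected (at most 1000 attempts).  ``scale_free``: preferential
    attachment adding ``param`` edges per new vertex (Barabasi-Albert),
    connected by construction with (n - param) * param edges.
    """
    if n < 2:
        raise ValueError("need at least 2 vertices")
    rng = np.random.default_rng(seed)
    if model == "erdos_renyi":
        for _ in range(_MAX_GNP_ATTEMPTS):
            g = nx.gnp_random_graph(n, param, seed=int(rng.integers(2**31)))
            if g.number_of_edges() and nx.is_connected(g):
                break
        else:
            raise RuntimeError(
                f"no connected G({n}, {param}) in {_MAX_GNP_ATTEMPTS} attempts"
            )
    elif model == "scale_free":
        g = nx.barabasi_albert_graph(n, int(param), seed=int(rng.integers(2**31)))
    else:
        raise ValueError(f"unknown graph model {model!r}")
    rename = {i: _vertex_name(i, n) for i in g.nodes}
    return load_graph([(rename[u], rename[v]) for u, v in g.edges()])


def sample_uniform_module(
    G: InteractionGraph, m: int, iterations: int, seed: int
) -> frozenset[str]:
    """A connected m-subgraph approximately uniform among all of them.

    Runs the constant-weight fixed-order chain (acceptance reduces to
    min{1, |nei(S)|/|nei(S')|}) for ``iterations`` steps and returns the
    final state.
    """
    if not (1 <= m <= G.n):
        raise ValueError(f"module order must satisfy 1 <= m <= n, got {m}")
    if m == G.n:
        return frozenset(G.vertex_ids)  # unique state
    rng = random.Random(seed)
    state = init_state(G, "fixed_order", m, rng, a=1.0, weights=None)
    for _ in range(iterations):
        v_minus = state.members.choose(rng)
        v_plus = state.frontier.choose(rng)
        old_nei = len(state.frontier)
        state.remove(v_minus)
        state.add(v_plus)
        if not state.is_connected():
            state.remove(v_plus)
            state.add(v_minus)
        elif len(state.frontier) > old_nei and \
                rng.random() >= old_nei / len(state.frontier):
            state.remove(v_plus)
            state.add(v_minus)
    return state.member_ids()


def generate_weights(
    G: InteractionGraph, module: frozenset[str], a: float, seed: int
) -> dict[str, float]:
    """Module vertices get beta(a, 1) p-values via inverse CDF U**(1/a);
    background vertices Uniform(0, 1).  Exact zeros are resampled."""
    if not (0.0 < a <= 1.0):
        raise ValueError("a must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for v in G.vertex_ids:
        u = rng.random()
        while u == 0.0:
            u = rng.random()
        out[v] = u ** (1.0 / a) if v in module else u
        while out[v] == 0.0:  # underflow of u**(1/a) at tiny a
            u = rng.random()
            out[v] = u ** (1.0 / a)
    return out


def generate_instance(
    n: int,
    model: Literal["erdos_renyi", "scale_free"] = "scale_free",
    m_fraction_range: tuple[float, float] = (0.05, 0.25),
    a_range: tuple[float, float] = (0.01, 0.5),
    seed: int = 0,
    *,
    graph_param: float | None = None,
    module_iterations: int | None = None,
) -> SyntheticInstance:
    """Compose graph, planted module and weights into one instance.

    The module order is uniform on the integer range
    [ceil(lo * n), floor(hi * n)] and the beta shape uniform on
    ``a_range``.  ``graph_param`` defaults to 2 attachment edges for
    scale-free graphs and to a mean degree of about 4 for Erdos-Renyi.
    """
    lo, hi = m_fraction_range
    if not (0.0 < lo <= hi < 1.0):
        raise ValueError("invalid module-fraction range")
    ss = np.random.SeedSequence(seed)
    s_graph, s_m, s_mod, s_w = (int(c.generate_state(1, np.uint32)[0])
                                for c in ss.spawn(4))
    if graph_param is None:
        graph_param = 2 if model == "scale_free" else min(4.0 / (n - 1), 0.5)
    G = random_connected_graph(n, model, graph_param, s_graph)
    m_lo, m_hi = math.ceil(lo * n), math.floor(hi * n)
    m_hi = max(m_lo, m_hi)
    rng = np.random.default_rng(s_m)
    m = int(rng.integers(m_lo, m_hi + 1))
    a = float(rng.uniform(*a_range))
    if module_iterations is None:
        module_iterations = max(10_000 * m // 100, 2_000)
    module = sample_uniform_module(G, m, module_iterations, s_mod)
    weights = generate_weights(G, module, a, s_w)
    return SyntheticInstance(
        graph=G,
        module=module,
        weights=weights,
        gen_params={
            "model": model, "n": n, "graph_param": graph_param, "m": m,
            "a": a, "seed": seed, "module_iterations": module_iterations,
        },
    )


def toy_instance(seed: int = 0) -> SyntheticInstance:
    """The small validation instance: a connected random graph on 30
    vertices with about 65 edges (Erdos-Renyi conditioned to 65 +/- 10%),
    a planted connected module of 9 vertices and beta(0.2, 1) module
    weights.  Small enough for the exact posterior oracle."""
    n, target_edges, m, a = 30, 65, 9, 0.2
    ss = np.random.SeedSequence(seed)
    s_graph, s_mod, s_w = (int(c.generate_state(1, np.uint32)[0])
                           for c in ss.spawn(3))
    p_edge = target_edges / (n * (n - 1) / 2)
    rng = np.random.default_rng(s_graph)
    for _ in range(_MAX_GNP_ATTEMPTS):
        G = random_connected_graph(n, "erdos_renyi", p_edge,
                                   int(rng.integers(2**31)))
        if abs(G.n_edges - target_edges) <= target_edges * 0.1:
            break
    else:  # pragma: no cover
        raise RuntimeError("could not hit the target edge count")
    module = sample_uniform_module(G, m, 20_000, s_mod)
    weights = generate_weights(G, module, a, s_w)
    return SyntheticInstance(
        graph=G, module=module, weights=weights,
        gen_params={"model": "erdos_renyi", "n": n, "edges": G.n_edges,
                    "m": m, "a": a, "seed": seed},
    )
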