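import random

import pytest

from softmodule import InteractionGraph, load_graph


@pytest.fixture
def path3() -> InteractionGraph:
    return load_graph([("A", "B"), ("B", "C")])


@pytest.fixture
def path4() -> InteractionGraph:
    return load_graph([("A", "B"), ("B", "C"), ("C", "D")])


@pytest.fixture
def star4() -> InteractionGraph:
    """Center c with leaves x, y, z."""
    return load_graph([("c", "x"), ("c", "y"), ("c", "z")])


@pytest.fixture
def cycle4() -> InteractionGraph:
    return load_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A")])


def random_graph(n: int, p: float, seed: int) -> InteractionGraph:
    """Small random connected graph for brute-force comparisons."""
    rng = random.Random(seed)
    while True:
        edges = [
            (f"v{i}", f"v{j}")
            for i in range(n)
            for j in range(i + 1, n)
            if rng.random() < p
        ]
        if not edges:
            continue
        try:
            g = load_graph(edges)
        except ValueError:
            continue
        if g.n == n:
            return g


def random_weights(G: InteractionGraph, seed: int) -> dict[str, float]:
    rng = random.Random(seed)
    return {v: rng.uniform(0.001, 1.0) for v in G.vertex_ids}
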