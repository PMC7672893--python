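"""Derived quantities over a sample of modules.

Given the MCMC sample set, this module answers the questions the soft
classification is for: probabilities of arbitrary boolean events about the
module, the false discovery rate of a reported vertex set, conditional
membership probabilities given the module order, and the expected AUC ROC
of a vertex ranking.

For a ranking v_1..v_n, membership probabilities p_i and a known module
order m, the expected AUC ROC has the closed form

    E[AUC] = 1 - (sum_i i*p_i - m(m+1)/2) / (m(n-m)).

When the order is itself random, the exact expectation is the mixture over
the sampled order distribution, E[AUC] = sum_m P(|M|=m) * E[AUC | m] with
the conditional probabilities p_i^(m) plugged into the closed form.  A
single-order weighting p'_i of the conditional probabilities is also
exposed; plugging the plain p_i in its place is a cheaper approximation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Mapping, Sequence

from .sampler import SampleCollection

__all__ = [
    "VertexPosterior",
    "event_probability",
    "set_fdr",
    "expected_auc",
    "expected_auc_unknown_order",
    "vertex_posterior",
]


@dataclass(frozen=True)
class VertexPosterior:
    """Marginal, conditional and order-weighted membership probabilities.

    ``p[v]`` is P(v in M); ``p_cond[(v, m)]`` is P(v in M | |M| = m);
    ``p_prime[v]`` is the order-weighted combination
    E(|M|*|G\\M|) * sum_m P(|M|=m) * p_cond[(v,m)] / (m(n-m));
    ``mean_order`` is E|M| under the sampled order distribution.
    """

    p: dict[str, float]
    p_cond: dict[tuple[str, int], float]
    p_prime: dict[str, float]
    mean_order: float
    order_dist: dict[int, float]


def event_probability(
    samples: SampleCollection, predicate: Callable[[frozenset[str]], bool]
) -> float:
    """Probability of an arbitrary boolean event about the module.

    ``predicate`` receives each sampled vertex set; the estimate is the
    fraction of samples where it holds.  Requires the chain to have been
    run with ``retain_samples``.
    """
    if samples.retained_samples is None:
        raise ValueError(
            "sample collection holds counts only; re-run the chain with "
            "retain_samples=True for event queries"
        )
    if not samples.retained_samples:
        raise ValueError("empty sample collection")
    hits = sum(1 for s in samples.retained_samples if predicate(s))
    return hits / len(samples.retained_samples)


def set_fdr(p: Mapping[str, float], V: Iterable[str]) -> float:
    """False discovery rate of a vertex set: mean of 1 - p_v over the set."""
    vs = list(V)
    if not vs:
        raise ValueError("empty vertex set")
    return sum(1.0 - p[v] for v in vs) / len(vs)


def expected_auc(
    ranking: Sequence[str], p: Mapping[str, float], m: int
) -> float:
    """Expected AUC ROC of a ranking for a module of known order ``m``.

    Rank index i is 1-based with i = 1 the most confident vertex.  The
    value is not clipped: results outside [0, 1] indicate probabilities
    inconsistent with ``m``.
    """
    n = len(ranking)
    if not (1 <= m < n):
        raise ValueError(f"module order m must satisfy 1 <= m < n, got {m}")
    weighted = sum(i * p[v] for i, v in enumerate(ranking, start=1))
    return 1.0 - (weighted - m * (m + 1) / 2.0) / (m * (n - m))


def vertex_posterior(samples: SampleCollection) -> VertexPosterior:
    """Marginal/conditional membership probabilities from sample counts."""
    if samples.n_samples < 1:
        raise ValueError("empty sample collection")
    n_s = samples.n_samples
    n = samples.graph.n
    order_dist = {m: c / n_s for m, c in sorted(samples.size_counts.items())}
    p = {v: samples.vertex_counts.get(v, 0) / n_s for v in samples.graph.vertex_ids}
    p_cond: dict[tuple[str, int], float] = {}
    for (v, m), c in samples.vertex_size_counts.items():
        p_cond[(v, m)] = c / samples.size_counts[m]
    mean_order = sum(m * q for m, q in order_dist.items())
    e_prod = sum(m * (n - m) * q for m, q in order_dist.items())
    p_prime: dict[str, float] = {}
    for v in samples.graph.vertex_ids:
        acc = 0.0
        for m, q in order_dist.items():
            if m == n:
                raise ValueError("a sampled module covers the whole graph; "
                                 "AUC is undefined (n - m = 0)")
            acc += q * p_cond.get((v, m), 0.0) / (m * (n - m))
        p_prime[v] = e_prod * acc
    return VertexPosterior(
        p=p, p_cond=p_cond, p_prime=p_prime, mean_order=mean_order,
        order_dist=order_dist,
    )


def expected_auc_unknown_order(
    ranking: Sequence[str],
    samples: SampleCollection,
    *,
    use_conditional: bool = True,
) -> float:
    """Expected AUC ROC of a ranking when the module order is not fixed.

    With ``use_conditional`` (default) the exact mixture over the sampled
    order distribution is computed: sum_m P(|M|=m) * E[AUC | m], each
    conditional term through the known-order closed form on p_i^(m).  When
    all samples share one order this reduces to :func:`expected_auc`.

    With ``use_conditional=False`` the marginal probabilities p_i are used
    as a drop-in approximation of the order-weighted p'_i:
    1 - (sum_i i*p_i - E[|M|(|M|+1)]/2) / E[|M|(n-|M|)].
    """
    post = vertex_posterior(samples)
    n = len(ranking)
    if n != samples.graph.n:
        raise ValueError("ranking must be a permutation of all graph vertices")
    if any(m >= n for m in post.order_dist):
        raise ValueError("a sampled module covers the whole graph; "
                         "AUC is undefined (n - m = 0)")
    if use_conditional:
        total = 0.0
        for m, q in post.order_dist.items():
            weighted = sum(
                i * post.p_cond.get((v, m), 0.0)
                for i, v in enumerate(ranking, start=1)
            )
            total += q * (1.0 - (weighted - m * (m + 1) / 2.0) / (m * (n - m)))
        return total
    e_prod = sum(m * (n - m) * q for m, q in post.order_dist.items())
    e_m_m1 = sum(m * (m + 1) * q for m, q in post.order_dist.items())
    weighted = sum(i * post.p[v] for i, v in enumerate(ranking, start=1))
    return 1.0 - (weighted - e_m_m1 / 2.0) / e_prod
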