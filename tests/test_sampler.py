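import math
import random
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from softmodule import (
    ChainConfig,
    acceptance_variable,
    estimate_vertex_probabilities,
    exact_posterior_fixed,
    is_connected_induced,
    load_graph,
    neighborhood,
    run_chain,
)
from softmodule.sampler import acceptance_fixed, init_state, propose_fixed

from conftest import random_graph, random_weights


class TestInitState:
    def test_singleton(self, path3):
        s = init_state(path3, "fixed_order", 1, seed_or_rng=0)
        assert s.order == 1
        (v,) = s.member_ids()
        assert s.frontier_ids() == path3.adjacency[v]

    def test_unique_connected_triple(self, path3):
        for seed in range(5):
            s = init_state(path3, "fixed_order", 3, seed_or_rng=seed)
            assert s.member_ids() == {"A", "B", "C"}

    def test_state_invariants(self):
        g = random_graph(12, 0.25, seed=1)
        for seed in range(5):
            s = init_state(g, "fixed_order", 5, seed_or_rng=seed)
            assert s.is_connected()
            assert s.frontier_ids() == neighborhood(g, s.member_ids())

    def test_k_too_large_rejected(self, path3):
        with pytest.raises(ValueError):
            init_state(path3, "fixed_order", 4, seed_or_rng=0)


class TestProposeFixed:
    def test_proposal_probability(self, path4):
        s = None
        for seed in range(100):  # find a seed landing on {B, C} (frontier {A, D})
            cand = init_state(path4, "fixed_order", 2, seed_or_rng=seed)
            if cand.member_ids() == {"B", "C"}:
                s = cand
                break
        assert s is not None
        rng = random.Random(0)
        for _ in range(10):
            s_prime, v_minus, v_plus, q = propose_fixed(path4, s, rng)
            assert q == pytest.approx(1 / 4)
            assert v_minus in {"B", "C"} and v_plus in {"A", "D"}
            assert s_prime == (s.member_ids() - {v_minus}) | {v_plus}


class TestAcceptanceFixed:
    def test_symmetric_swap_is_certain(self, cycle4):
        w = {v: 0.3 for v in cycle4.vertex_ids}
        rho = acceptance_fixed(cycle4, w, 0.5, {"A", "B"}, {"B", "C"}, "A", "C")
        assert rho == pytest.approx(1.0)

    def test_uniform_signal_limit_keeps_frontier_term(self, path4):
        w = {v: 0.5 for v in path4.vertex_ids}
        # S={A,B} (nei = {C}), S'={B,C} (nei = {A, D})
        rho = acceptance_fixed(path4, w, 1.0, {"A", "B"}, {"B", "C"}, "A", "C")
        assert rho == pytest.approx(1 / 2)

    def test_stronger_pvalue_always_accepted(self, cycle4):
        w = {"A": 0.1, "B": 0.3, "C": 0.3, "D": 0.01}
        # equal frontier sizes; weight term (w_+ / w_-)^(a-1) decides
        rho = acceptance_fixed(cycle4, w, 0.5, {"A", "B"}, {"B", "C"}, "A", "C")
        assert rho == pytest.approx((0.3 / 0.1) ** -0.5)  # weaker v_+ damps
        rho2 = acceptance_fixed(cycle4, w, 0.5, {"A", "B"}, {"A", "D"}, "B", "D")
        assert rho2 == 1.0  # (0.01/0.3)^(-0.5) = sqrt(30) > 1

    def test_disconnected_proposal_rejected(self, path4):
        w = {v: 0.5 for v in path4.vertex_ids}
        rho = acceptance_fixed(path4, w, 0.5, {"B", "C"}, {"B", "D"}, "C", "D")
        assert rho == 0.0


class TestAcceptanceVariable:
    def test_threshold_weight_addition_is_certain(self, cycle4):
        tau = 0.05
        w = {v: tau for v in cycle4.vertex_ids}
        # S={A,B}: closed nbhd = all 4; S'={A,B,C}: closed nbhd = all 4
        rho = acceptance_variable(cycle4, w, 0.3, tau, {"A", "B"}, {"A", "B", "C"})
        assert rho == pytest.approx(1.0)

    def test_cut_vertex_removal_rejected(self, path3):
        w = {v: 0.5 for v in path3.vertex_ids}
        rho = acceptance_variable(path3, w, 0.3, 0.01, {"A", "B", "C"}, {"A", "C"})
        assert rho == 0.0

    def test_detailed_balance_exhaustive(self):
        """pi(S) * P(S -> S') == pi(S') * P(S' -> S) for every neighboring
        state pair on a 5-vertex graph, with pi(S) ~ prod (w_v/tau)^(a-1)."""
        g = load_graph([("A", "B"), ("B", "C"), ("C", "D"), ("D", "A"), ("C", "E")])
        rng = random.Random(42)
        w = {v: rng.uniform(0.01, 1.0) for v in g.vertex_ids}
        a, tau = 0.3, 0.1

        states = [
            frozenset(c)
            for r in range(1, 6)
            for c in combinations(g.vertex_ids, r)
            if is_connected_induced(g, set(c))
        ]
        log_pi = {
            s: sum((a - 1.0) * (math.log(w[v]) - math.log(tau)) for v in s)
            for s in states
        }

        def transition(s, s_prime):
            closed = len(s | neighborhood(g, s))
            return acceptance_variable(g, w, a, tau, s, s_prime) / closed

        checked = 0
        for s in states:
            for s_up in states:
                if len(s_up) == len(s) + 1 and s < s_up:
                    lhs = math.exp(log_pi[s]) * transition(s, s_up)
                    rhs = math.exp(log_pi[s_up]) * transition(s_up, s)
                    assert lhs == pytest.approx(rhs, rel=1e-12)
                    checked += 1
        assert checked > 10


class TestRunChain:
    def test_uniform_occupancy_on_cycle(self, cycle4):
        """Constant weights, a=1, k=2: the stationary law is uniform over
        the four edges of the cycle (thinned chi-square at alpha=0.01)."""
        config = ChainConfig(mode="fixed_order", a=1.0, k=2,
                             n_iterations=100_000, burn_in=1_000, seed=5,
                             retain_samples=True)
        samples = run_chain(cycle4, None, config)
        thinned = samples.retained_samples[::10]
        counts = {}
        for s in thinned:
            counts[s] = counts.get(s, 0) + 1
        assert len(counts) == 4
        _, pval = stats.chisquare(list(counts.values()))
        assert pval > 0.01

    def test_trace_bookkeeping(self, cycle4):
        config = ChainConfig(mode="fixed_order", a=1.0, k=2,
                             n_iterations=5_000, burn_in=100, seed=0,
                             trace_every=250)
        samples = run_chain(cycle4, None, config)
        assert len(samples.trace) == 5_000 // 250
        assert samples.n_samples == 5_000 - 100

    def test_fixed_order_samples_connected_of_order_k(self):
        g = random_graph(10, 0.3, seed=2)
        w = random_weights(g, seed=2)
        config = ChainConfig(mode="fixed_order", a=0.4, k=4,
                             n_iterations=3_000, burn_in=100, seed=1,
                             retain_samples=True)
        samples = run_chain(g, w, config)
        assert set(samples.size_counts) == {4}
        for s in samples.retained_samples[::100]:
            assert len(s) == 4
            assert is_connected_induced(g, s)

    def test_counting_identities(self):
        g = random_graph(9, 0.3, seed=3)
        w = random_weights(g, seed=3)
        config = ChainConfig(mode="variable_order", a=0.3, tau=0.05,
                             n_iterations=10_000, burn_in=500, seed=2)
        samples = run_chain(g, w, config)
        samples.check()
        p = estimate_vertex_probabilities(samples)
        mean_order = sum(m * c for m, c in samples.size_counts.items()) / samples.n_samples
        assert sum(p.values()) == pytest.approx(mean_order)

    def test_reproducibility(self):
        g = random_graph(10, 0.3, seed=4)
        w = random_weights(g, seed=4)
        config = ChainConfig(mode="variable_order", a=0.3, tau=0.05,
                             n_iterations=5_000, burn_in=100, seed=9)
        s1 = run_chain(g, w, config)
        s2 = run_chain(g, w, config)
        assert s1.vertex_counts == s2.vertex_counts
        assert s1.size_counts == s2.size_counts
        assert s1.trace == s2.trace
        s3 = run_chain(g, w, ChainConfig(mode="variable_order", a=0.3, tau=0.05,
                                         n_iterations=5_000, burn_in=100, seed=10))
        assert s3.vertex_counts != s1.vertex_counts

    def test_long_run_converges_to_exact_posterior(self):
        """Total-variation distance to the enumerated posterior shrinks as
        the chain runs longer (10^4 vs 10^5 iterations)."""
        g = random_graph(8, 0.35, seed=5)
        w = random_weights(g, seed=5)
        a, k = 0.4, 3
        exact = exact_posterior_fixed(g, w, a, k)

        def tv(n_iter):
            config = ChainConfig(mode="fixed_order", a=a, k=k,
                                 n_iterations=n_iter, burn_in=1_000, seed=6)
            est = estimate_vertex_probabilities(run_chain(g, w, config))
            return 0.5 * sum(abs(est[v] - exact[v]) for v in g.vertex_ids)

        tv_short, tv_long = tv(10_000), tv(100_000)
        assert tv_long < tv_short
        assert tv_long < 0.02

    def test_independent_runs_bernoulli_error(self):
        """With R independent runs each probability estimate behaves like a
        Bernoulli proportion: |p_hat - p| <= 4*sqrt(p(1-p)/R) for at least
        95% of (repetition, vertex) pairs."""
        g = random_graph(7, 0.4, seed=6)
        w = random_weights(g, seed=6)
        a, k, runs = 0.4, 3, 100
        exact = exact_posterior_fixed(g, w, a, k)
        inside = total = 0
        for rep in range(10):
            config = ChainConfig(mode="fixed_order", a=a, k=k,
                                 n_iterations=300, strategy="independent_runs",
                                 n_runs=runs, seed=100 + rep, burn_in=0)
            est = estimate_vertex_probabilities(run_chain(g, w, config))
            for v in g.vertex_ids:
                p = exact[v]
                bound = 4 * math.sqrt(max(p * (1 - p), 1e-12) / runs)
                inside += abs(est[v] - p) <= bound + 1e-9
                total += 1
        assert inside / total >= 0.95

    def test_unweighted_vertex_rejected(self, path3):
        config = ChainConfig(mode="fixed_order", a=0.5, k=2,
                             n_iterations=100, burn_in=10, seed=0)
        with pytest.raises(ValueError, match="unweighted"):
            run_chain(path3, {"A": 0.5, "B": 0.5}, config)
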