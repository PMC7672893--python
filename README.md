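# softmodule

Soft classification for the **active module identification problem** in
interaction networks.

Given a protein–protein interaction graph *G* and a differential-expression
p-value for every vertex, classical tools (jActiveModules, BioNet) return a
single "best" connected subnetwork — a hard classification that offers no
way to tell a confident member from a vertex that merely glues the module
together. `softmodule` instead estimates, for every vertex *v*, the
posterior probability

P(v ∈ M | W = w)

that *v* belongs to the active module M, by Metropolis–Hastings sampling of
connected subgraphs from the posterior. The probabilities then give, for
free:

* the **FDR of any reported vertex set** V: (1/|V|) Σ_{v∈V} P(v ∉ M | W=w);
* probabilities of arbitrary boolean events about M ("pathway 1 or
  pathway 2 is hit");
* the **expected AUC ROC** of any vertex ranking, in closed form:
  for a ranking v₁…vₙ and module order m,
  E[AUC] = 1 − (Σᵢ i·pᵢ − m(m+1)/2) / (m(n−m));
* a **connectivity-preserving ranking**: an ordering whose every prefix
  induces a connected subgraph, so that cutting it at any FDR level q
  yields a *nested* family of connected modules M(q) — a vertex present at
  FDR 0.05 can never vanish at FDR 0.25.

It is intended for computational biologists analysing transcriptomic (or
proteomic/metabolomic) contrasts on an interaction network, especially when
few replicates rule out resampling-based support values.

## Model

P-values follow a beta-uniform mixture (BUM): noise vertices are
Uniform(0,1), module vertices β(a,1) with shape a ∈ (0,1), mixture weight λ
for the uniform part; the density is λ + (1−λ)·a·x^(a−1). Two samplers are
provided:

* **fixed order** — states are connected k-subgraphs (k estimated as
  (1−λ)·n); one step swaps a member for a frontier vertex, acceptance
  ρ = min{1, (w₊/w₋)^(a−1) · |nei(S)|/|nei(S′)|};
* **variable order** — states are all non-empty connected subgraphs; one
  step adds or removes a single vertex, each extra vertex penalised by a
  prior factor a·τ^(a−1) (τ is a p-value confidence threshold, default
  10⁻⁷), giving stationary law π(S) ∝ Π_{v∈S} (w_v/τ)^(a−1).

Because the optimal connectivity-preserving ranking problem is NP-hard
(there is a reduction from Exact Cover by 3-Sets, shipped as a test
fixture), the ranking uses an O(n³) peeling heuristic: repeatedly split off
the block with the worst average FDR and assign it the worst remaining
ranks.

## Worked example

```python
from softmodule import (
    toy_instance, fit_bum, estimate_module_order, ChainConfig, run_chain,
    estimate_vertex_probabilities, exact_posterior_fixed, ocpr_heuristic,
    module_at_fdr, expected_auc, set_fdr,
)

inst = toy_instance(seed=1)          # 30 vertices, ~65 edges, 9-vertex module
G, w = inst.graph, inst.weights

params = fit_bum(w)
print(f"fitted BUM: lambda={params.lam:.3f} a={params.a:.3f} "
      f"-> estimated module order k={estimate_module_order(params, G.n)}")

config = ChainConfig(mode="fixed_order", a=0.2, k=9,
                     n_iterations=1_000_000, burn_in=25_000, seed=0)
probs = estimate_vertex_probabilities(run_chain(G, w, config))
exact = exact_posterior_fixed(G, w, a=0.2, k=9)   # exhaustive enumeration

top = sorted(G.vertex_ids, key=lambda v: -probs[v])[:3]
for v in top:
    print(f"{v}: estimated P(v in M) = {probs[v]:.3f}  exact = {exact[v]:.3f}")

ranking = ocpr_heuristic(G, probs)
print(f"expected AUC ROC of the ranking: {expected_auc(ranking.order, probs, 9):.3f}")
module = module_at_fdr(ranking, probs, q=0.25)
print(f"module at FDR 0.25: {len(module)} vertices, "
      f"FDR = {set_fdr(probs, module):.3f}")
```

prints

```
fitted BUM: lambda=0.704 a=0.229 -> estimated module order k=9
g00: estimated P(v in M) = 0.999  exact = 1.000
g20: estimated P(v in M) = 0.992  exact = 0.991
g16: estimated P(v in M) = 0.974  exact = 0.973
expected AUC ROC of the ranking: 0.868
module at FDR 0.25: 8 vertices, FDR = 0.236
```

The MCMC estimates agree with the exactly enumerated posterior to three
decimals on this instance; the maximum-likelihood fit recovers the planted
module order (k = 9); and the extracted FDR-0.25 module indeed has an
estimated false discovery rate just under 0.25.

The same workflow is available from the shell:

```
softmodule simulate --n 100 --seed 1 --out-prefix inst
softmodule full --graph inst.graph.tsv --weights inst.weights.tsv \
    --out-dir results --seed 1 --fdr 0.05,0.15,0.25
```

which writes vertex probabilities, the connectivity-preserving ranking, the
log-likelihood trace (for mixing-time diagnostics) and one nested module
per FDR level. See `softmodule --help` for the other subcommands
(`fit-bum`, `sample`, `oracle`, `rank`, `module`, `auc`).

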