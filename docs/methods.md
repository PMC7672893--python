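# Methods

## Problem and model

The input is an undirected, simple, connected interaction graph *G* on *n*
vertices (gene/protein identifiers) and a weight w(v) ∈ (0,1] per vertex —
the p-value of a per-gene differential test. The generative model: an
unknown connected subgraph M (the *active module*) whose vertices carry
independent β(a,1)-distributed p-values (a < 1, so small p-values are
enriched), while all other vertices carry independent Uniform(0,1)
p-values. Marginally the p-values follow the beta-uniform mixture (BUM)
density λ + (1−λ)·a·x^(a−1), λ being the weight of the uniform (noise)
component. The target of inference is not a single best module but the
posterior membership probability P(v ∈ M | W = w) of every vertex — soft
classification.

Disconnected input graphs are reduced to their largest connected component
(ties toward the component containing the lexicographically smallest id),
with a logged count of dropped vertices; this mirrors the standard
preprocessing of interaction networks and keeps every downstream algorithm
on a connected graph. Vertex identity is an opaque string, and every
tie-break in the package falls back to lexicographic order on ids, which
makes all outputs deterministic given a seed.

## BUM fit

`fit_bum` maximises Σ_v log(λ + (1−λ)·a·w_v^(a−1)) with bounded L-BFGS-B
on [10⁻⁶, 1−10⁻⁶]² from a 3×3 grid of starts (λ₀, a₀ ∈ {0.2, 0.5, 0.8}).
P-values of exactly 0 are clamped to 10⁻¹⁶ before any use of x^(a−1).
The likelihood is not identifiable on signal-free data: λ→0 with a→1
mimics the uniform density exactly as λ→1 does. Among converged optima
whose log-likelihoods differ by less than 0.5 (statistically
indistinguishable), the fit therefore returns the one with the largest λ,
so absence of signal is always expressed through the mixture weight and
never through a ≈ 1. The module-order point estimate is
k = round((1−λ)·n) (round-half-to-even), clamped to [1, n−1].

## Samplers

Both chains are plain Metropolis–Hastings kernels over connected
subgraphs; all likelihood arithmetic is in log space and the frontier
nei(S) (vertices at distance 1 from S) is maintained incrementally via
per-vertex counts of neighbours inside S, so a step costs O(deg) plus one
BFS over the state for the connectivity gate.

**Fixed order.** The state is a connected k-subgraph. A step draws v₋
uniformly from S and v₊ uniformly from nei(S) *computed before the
removal* — this makes the proposal probability exactly
Q(S′|S) = 1/(|nei(S)|·|S|) — and accepts with
ρ = min{1, (w₊/w₋)^(a−1) · |nei(S)|/|nei(S′)|}; a disconnected S′ is
generated and rejected through ρ = 0 rather than excluded from the
proposal set (that is what keeps the printed Q correct). The stationary
law is the posterior under a uniform prior over connected k-subgraphs,
with subgraph likelihood Π_{v∈S} a·w_v^(a−1).

**Variable order.** The state is any non-empty connected subgraph. One
vertex is drawn uniformly from the closed neighbourhood nei(S) ∪ V(S): a
frontier pick proposes an addition, a member pick a removal. Each extra
vertex is penalised by a prior factor a·τ^(a−1) (τ: confidence threshold
on p-values, default 10⁻⁷, matching common practice for expression data),
giving the stationary law π(S) ∝ Π_{v∈S}(w_v/τ)^(a−1) and acceptance
ratios (w₊/τ)^(a−1) resp. (τ/w₋)^(a−1) times
|nei(S)∪V(S)| / |nei(S′)∪V(S′)|. The empty module is not a state: a
removal proposed from a singleton is rejected and the state repeats,
keeping the chain on non-empty connected subgraphs (the likelihood of the
empty set is undefined). Detailed balance of this kernel against the
closed-form π is verified exhaustively on a 5-vertex state space in the
test suite.

**Sample collection.** Either one long run — every visited state after the
burn-in T contributes one sample, *including* repeats after rejections
(occupancy time is what estimates the stationary law; without repeats the
estimator would be inconsistent) — or R independent runs contributing only
their final states, which makes every event estimate a Bernoulli
proportion with variance p(1−p)/R. The default burn-in is 25,000
iterations, an empirically adequate mixing time for interaction networks
of a few thousand vertices; the log-likelihood trace (recorded every
`trace_every` iterations) lets users re-derive T per instance. Chains are
driven by Python's Mersenne-Twister `random.Random(seed)` and are exactly
reproducible; independent runs draw child seeds from a
`numpy.random.SeedSequence`.

## Posterior queries

Membership probabilities are occurrence frequencies over the sample set.
The FDR of a vertex set is the mean of 1 − p_v over the set. For a ranking
v₁…vₙ and known module order m the expected AUC ROC has the closed form
1 − (Σᵢ i·pᵢ − m(m+1)/2)/(m(n−m)); ranking by descending pᵢ maximises it
(verified exhaustively over all permutations for small n). When the order
is random, the package computes the exact mixture
Σ_m P(|M|=m|W=w) · E[AUC | m] from the per-order conditional
probabilities p_i^(m); this equals the sample-by-sample average of
empirical AUCs and reduces to the closed form when all samples share one
order. A single-vector summary p′ᵢ — the conditional probabilities
weighted by P(|M|=m)/(m(n−m)) and rescaled by E(|M|·|G∖M|) — is exposed
on `VertexPosterior`, and a flag allows the cheaper approximation that
plugs the marginal pᵢ into the mixture normalisation instead. Orders never
observed in the sample carry zero weight and are excluded. Conditional
queries fail loudly when a sampled module covers the whole graph
(n − m = 0 leaves the AUC undefined).

## Connectivity-preserving ranking

A ranking is connectivity preserving (CP) when every prefix induces a
connected subgraph; thresholding prefix FDR at any level q then yields
nested connected modules M(q). Finding the CP ranking with maximal
expected AUC is NP-hard (the package ships the constructive reduction from
Exact Cover by 3-Sets as an oracle fixture: hub vertex p=1, one p=0 vertex
per triple, element vertices at ε = 1/(12q(q+1)); an exact cover exists
iff some CP ranking reaches objective Σ i·pᵢ = 3/2). The heuristic peels
the graph from the back: at each step, for every vertex v, split the
current graph G_k into the largest component G^(v) of G_k∖{v} and the
block H = G_k∖G^(v); the v maximising the average FDR of H wins (ties:
smaller |H| to peel conservatively, then smaller id), H is assigned the
worst |H| remaining ranks, and the algorithm recurses on G^(v). Each step
is O(n²), the whole ranking O(n³); a 2,000-vertex network takes a few
minutes in pure Python.

The peeling assigns one rank to the whole block H, but prefix extraction
needs a total order, and an arbitrary order inside H can break prefix
connectivity (H may be several fragments hanging off v). Inside each block
the package therefore repeatedly places earliest the highest-probability
block vertex adjacent to the surviving component or to an already placed
block vertex (ties: smaller id). This within-block order is our extension
of the block-rank scheme; it preserves connectivity by construction and
favours confident vertices. Prefix connectivity of the final order is
asserted before returning.

## Exact oracles

For small instances everything is computed exactly: connected k-subgraphs
are enumerated once each by recursive extension with exclusion over
per-vertex adjacency bitmasks (root = minimum-index vertex); posterior
scores use the cancelled forms w_v^(a−1) (the a^k factor is common) and
(w_v/τ)^(a−1), normalised by log-sum-exp. A safety budget (default 5·10⁷
enumerated subgraphs) makes oracle calls fail fast rather than hang.
`brute_force_ocpr` enumerates CP rankings by recursive prefix extension
with branch-and-bound on the partial objective (n ≤ 10). These oracles
back the tests; they are never a runtime substitute for the sampler.

## Synthetic data

The generator reproduces the simulation conditions the method is
validated under: scale-free graphs (preferential attachment, 2 edges per
new vertex) or Erdős–Rényi graphs resampled until connected; a planted
module drawn uniformly at random among connected m-subgraphs, with m
uniform on 5%–25% of the graph order; module p-values β(a,1) with a
uniform on [0.01, 0.5] via inverse-CDF U^(1/a), background Uniform(0,1).
Uniform module sampling runs the constant-weight fixed-order chain (its
stationary law is uniform over connected m-subgraphs; rejection sampling
is hopeless at realistic m), with a burn-in heuristic of 10⁴·(m/100)
iterations. The small validation instance is a 30-vertex Erdős–Rényi
graph conditioned to 65 ± 10% edges with a planted 9-vertex β(0.2,1)
module — small enough for the exact posterior oracle, yet structured
enough that the posterior is nontrivial.

What the generator does *not* emulate: the degree correlations and hub
biology of real interactomes, correlated p-values from co-regulated genes,
module boundaries blurred by partial activation, and replicate-level
expression matrices. Passing benchmarks therefore demonstrate correctness
of the inference machinery under the stated model, not performance on any
particular real dataset.

## Problem sizes and numerical conventions

The validation suite uses: 10⁶ chain iterations (burn-in 25,000) against
the enumerated posterior on the 30-vertex instance; 50 scale-free
instances of 100 vertices with 20,000-iteration chains for the ranking
benchmark; 20 datasets of 10⁴ p-values for mixture recovery; exhaustive
checks (all subsets, all permutations, all CP rankings) on graphs of up to
10 vertices. Occupancy chi-square tests thin the chain (every 10th sample)
so the test statistic is computed on effectively independent draws.
Degenerate inputs: k = n is allowed as the unique full-graph state for
initialisation and uniform module draws, but chains require k < n so the
frontier is never empty; empty vertex sets are rejected wherever a mean
over the set is taken.

## Limitations

* The membership probabilities are Monte-Carlo estimates; their accuracy
  is bounded by the effective sample size, and strongly multimodal
  posteriors (several well-separated candidate modules) mix slowly under
  the single-swap kernel. The log-likelihood trace is the diagnostic.
* The peeling heuristic carries no optimality guarantee (the underlying
  problem is NP-hard); on random 8-vertex instances it is close to, but
  not always at, the exhaustive optimum.
* The variable-order prior has a single resolution knob τ; results on
  real data should be read jointly with the trace and with more than one
  FDR level, as in any threshold-based module method.
* Edge weights, directed interactions and multigraphs are out of scope.
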