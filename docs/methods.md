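# Methods

## Model

A network is an undirected, unweighted graph `G = (V, E)` on `n` nodes,
`|E| = m` edges, self-edges allowed. The adjacency matrix is binary with
`A_ii = 1` exactly when the self-edge `(i, i)` exists; the degree is the row
sum `k_v = Σ_j A_vj`, so a self-edge contributes **1** (not 2) to its
endpoint's degree; the Laplacian is `L = D − A` with `D = diag(k)`. Applying
these definitions literally has one notable consequence: a self-edge raises
`D_ii` and `A_ii` equally, so it cancels in `L` and is invisible to the
classical walk dynamics — it only enters through the degree weighting of the
score and through the candidate set. A node whose only edge is a self-edge has
`L_ii = 0` and never moves.

### Walk propagators

* Classical (CRW): a Markov process with rate matrix `Q = −L` (an independent
  unit-rate exponential clock on every incident edge), giving
  `P(t) = exp(−tL)`. This is the real matrix exponential: it is the only
  probability-conserving reading, with rows summing to 1 for all `t ≥ 0`.
* Quantum (QW): unitary evolution `U(t) = exp(−itH)` with `H = A` (QW-A) or
  `H = L` (QW-L); measurement probabilities `P_ij(t) = |U_ij(t)|²`.

Because `A` and `L` are real symmetric, every propagator is symmetric and
row-stochastic; on a connected graph the CRW converges to the uniform matrix
`1/n`. Cross-component entries are exactly zero for all walk kinds.

Propagators are computed by exact eigendecomposition of the generator
(`scipy.linalg.eigh`), with complex arithmetic confined to the phase factors
`exp(−itλ)`. This keeps stochasticity and unitarity at rounding error and
makes unit tests bit-stable. A scaled-and-squared 50-term Taylor backend
(`backend="taylor"`) is retained as an independent numerical cross-check; the
dense eigendecomposition costs `O(n³)` time and `O(n²)` memory, which is the
intended operating regime (dense graphs up to a few tens of thousands of
nodes, given RAM).

### Scores

For a non-edge with `i ≠ j`: `S = P_ij(t) (k_i + k_j)` — the transition
probability scaled by endpoint degrees, a preferential-attachment-style
weighting. For an absent self-edge: `S = ½ Σ_{u∈N(i)} P_iu(t)`, half the
probability mass on the node's neighbourhood. A self-pair of an isolated node
scores 0 (empty sum). Scores are nonnegative and symmetric in `(i, j)`.

The walk duration is `t = c/⟨k⟩` by default. `1/⟨k⟩` is the expected holding
time of the classical walker at a typical node, so small multiples probe the
near field without washing out to the stationary distribution; `c = 2` is the
package default (a value in the 2–4 range works across the sparse networks
this method targets, and the CLI exposes both `--time-multiple` and an
explicit `--time`). Both `⟨k⟩` and the degrees in the score are taken from
the graph actually being scored — after any edge removal — because the
predictor can only see the reduced graph.

Ranking sorts by descending score with ties broken by node-index-lexicographic
pair order, so rankings are deterministic. By default every non-edge,
including every absent self-pair, is a candidate; `include_self=False` (CLI
`--no-self`) restricts to distinct pairs, and the evaluation harness has a
separate `score_self_pairs=False` ablation that keeps self-pairs in the
candidate set but scores them 0 for all methods.

### Baselines

* **L3**: `S(x,y) = Σ_{u,v} A_xu A_uv A_vy / √(k_u k_v)` — degree-normalised
  count of length-3 paths. Self-edges are excluded from both the path
  enumeration and the normalising degrees (the simple-graph projection);
  a 3-path through a self-edge is not a meaningful docking geometry and the
  original formulation assumes simple graphs.
* **PA** `k_i k_j`, extended to `k_i²` for self-pairs — the only baseline with
  a natural self-edge score.
* **CN** `|N(i) ∩ N(j)|` and **AA** `Σ_z 1/log k_z` over common neighbours
  (full degrees; a common neighbour always has `k ≥ 2`, so the logarithm is
  safe).
* **SPM** (structural perturbation method): per run, a uniformly random 10%
  of the edges form the perturbation `ΔA`; the remaining adjacency matrix
  `A_R` is eigendecomposed, each eigenvalue receives the first-order
  correction `Δλ_k = x_kᵀ ΔA x_k / x_kᵀ x_k` while eigenvectors are kept, and
  non-edges are scored by the reconstructed matrix averaged over 10 runs
  (`p_H = 0.1`, 10 runs are the standard settings and the defaults).
  First-order non-degenerate perturbation theory is ambiguous inside a
  degenerate eigenspace, where the computed eigenbasis is arbitrary; we treat
  eigenvalues with gap < 1e−10 as one block and average their corrections,
  which makes the reconstruction basis-independent.

L3, CN and AA score absent self-pairs as 0: those heuristics have no defined
self-interaction score, and scoring them 0 (rather than dropping them) keeps
every method on the identical candidate set.

## Evaluation protocol

`make_split` removes `⌊P·m⌋` edges uniformly at random (self-edges removable
like any edge) as positive test cases; **all** non-edges of the original
graph, including absent self-pairs, are negatives. The default sweep is
`P ∈ {0.1, …, 0.5}` with 10 repetitions. Within a repetition all methods see
the same split (paired comparison — lower variance than independent splits);
each `(P, repetition)` cell derives its own child seed from the master seed
via `SeedSequence` spawn keys, so any cell is reproducible in isolation.

Metrics: **AuPR** is non-interpolated average precision over the
descending-score threshold sweep, with tied scores processed as one threshold
block — the conservative integrator under the extreme class imbalance of
sparse networks (positives are `O(m)`, negatives `O(n²)`). **AuROC** is the
Mann–Whitney probability that a random positive outscores a random negative,
ties credited ½. Both are computed by scikit-learn
(`average_precision_score`, `roc_auc_score`), which implements exactly these
conventions; the test suite checks them against exhaustive enumeration.
A method that cannot score a candidate scores it 0; candidates are never
dropped.

## Synthetic generator

`generate_clustered_scalefree` grows a graph by preferential attachment with
a triad-formation step (Holme–Kim growth rules): each new node makes
`m_attach` links; the first is always preferential attachment (sampling
proportional to degree + 1, with the `m_attach` founder nodes seeded into the
pool), and each subsequent link closes a triangle with a random neighbour of
the previous attachment target with probability `triad_prob`, falling back to
preferential attachment when no eligible neighbour exists. This keeps
`⟨k⟩ ≈ 2·m_attach` across the whole `triad_prob` range while average
clustering rises from the scale-free baseline (~0.03 at `n = 1000`,
`m_attach = 5`) to ~0.45 — the knob used to study how clustering shifts the
classical/quantum balance. Optional post-hoc self-edges (`self_edge_prob`,
default 0) emulate self-interacting proteins.

What the generator does **not** emulate: degree-degree disassortativity of
curated interactomes, community structure, experimental false positives, or
the ascertainment bias of literature-curated edges. Passing benchmarks on
these graphs demonstrates correctness of the pipeline and the direction of
the clustering effect, not absolute performance on real interactomes.

## Problem sizes and numerical choices

The bundled end-to-end checks run at desk scale, chosen so the full suite
completes in minutes on one CPU: benchmark graphs of `n = 500`,
`m_attach = 4` (⟨k⟩ ≈ 8) with 50% removal and 5 repetitions; return
probability diagnostics at `n = 300`; a clustering sweep of
`triad_prob ∈ {0, 0.25, 0.5, 0.75, 1}` × 10 seeds at `n = 500`. At these
sizes the qualitative findings are stable across seeds: every predictor
beats chance, node-averaged return probabilities order QW-L ≥ QW-A ≥ CRW
throughout `t ∈ (0, 2)` (the Laplacian's degree diagonal localises the
quantum walker), and the slope of AuPR(QW-A) − AuPR(CRW) against average
clustering is negative.

Tolerances: row sums and symmetry of propagators are asserted at 1e−9
absolute, the CRW semigroup law at 1e−8, brute-force score agreement at
1e−10, and Laplacian positive semidefiniteness at −1e−10 on the smallest
eigenvalue. Propagator entries are clipped to `[0, 1]` after exponentiation
(rounding can produce entries like −1e−17).

## Known limitations

* Dense `O(n²)` memory and `O(n³)` eigendecompositions; no sparse/Krylov
  propagators. Full candidate enumeration is `O(n²)`.
* The walk duration is a single global `t`; per-node or location-dependent
  times are out of scope.
* Table-style network statistics treat the simple-graph projection for
  density/clustering/assortativity by choice; conventions that count a
  self-edge as 2 in the degree would shift `⟨k⟩` (and hence `t = c/⟨k⟩`)
  slightly on self-edge-rich graphs.
* SPM's first-order reconstruction degrades as the perturbation fraction
  grows; the implementation follows the original recipe and is not intended
  for large `p_H`.
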