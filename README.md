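# walklink

Link prediction on undirected graphs with **continuous-time classical and
quantum walks**, built for sparse interaction networks such as protein–protein
interaction (PPI) maps. Experimentally determined interactomes are incomplete
and noisy; ranking the unobserved node pairs by how likely they are to be true
interactions is a standard way to prioritise them. Most popular predictors
(common neighbours, Adamic–Adar, the PPI-specific L3 path counter) only see a
node's immediate vicinity and cannot score self-interactions at all. A
continuous-time walk explores the whole connected component and assigns a
score to *every* candidate pair — including absent self-edges, the network
signature of self-interacting proteins.

## The method

For a graph `G` with adjacency matrix `A`, degree matrix `D` and Laplacian
`L = D − A`:

* **CRW** — classical random walk with rate matrix `Q = −L`, transition
  probabilities `P(t) = exp(−tL)`;
* **QW-A / QW-L** — quantum walk with unitary `U(t) = exp(−itH)`, Hamiltonian
  `H = A` or `H = L`, and measurement probabilities
  `P_ij(t) = |⟨j| exp(−itH) |i⟩|²`.

Both matrices are row-stochastic and symmetric. A non-edge `(i, j)` is scored

```
S(i, j; t) = P_ij(t) · (k_i + k_j)        i ≠ j
S(i, i; t) = ½ · Σ_{u ∈ N(i)} P_iu(t)     absent self-edge
```

with `k_v = Σ_j A_vj` (a self-edge adds 1 to its endpoint's degree). The walk
duration defaults to `t = c/⟨k⟩`, a small multiple of the time a classical
walker needs to leave a typical node; `c = 2` is the package default.

The package also implements five reference predictors (L3, preferential
attachment, common neighbours, Adamic–Adar, and the structural perturbation
method), an edge-removal cross-validation harness scored by AuPR and AuROC,
and a scale-free graph generator with tunable clustering for controlled
experiments.

## Worked example

Score the non-edges of the 4-node path `1–2–3–4` with the adjacency-Hamiltonian
quantum walk at `t = 2/⟨k⟩`:

```bash
$ printf '1 2\n2 3\n3 4\n' > path4.tsv
$ walklink stats --graph path4.tsv
{
  "n_nodes": 4,
  "n_edges": 3,
  "avg_degree": 1.5,
  "density": 0.5,
  "avg_clustering": 0.0,
  "assortativity": -0.5000000000000001,
  "sip_count": 0
}
$ walklink score --graph path4.tsv --method qw --hamiltonian adjacency --time-multiple 2
node_i	node_j	score	rank
2	4	0.9118417178312493	1
1	3	0.911841717831249	2
2	2	0.32538721811622284	3
3	3	0.3253872181162227	4
1	1	0.2454664593541269	5
4	4	0.24546645935412673	6
1	4	0.18103854066846697	7
```

All seven candidates are ranked: three distinct non-adjacent pairs and four
absent self-edges. The walker moving from node 2 reaches node 4 (two hops)
with high probability at this `t`, and the mirror pair `(1, 3)` ties with it
by symmetry; the long-range pair `(1, 4)` scores lowest. The same library
calls are available in Python:

```python
from walklink import Graph, WalkSpec, rank_candidates, default_time

g = Graph([(1, 2), (2, 3), (3, 4)])
table = rank_candidates(g, WalkSpec("qw", default_time(g, 2.0), "adjacency"))
```

A full cross-validation comparison (here on a generated clustered scale-free
graph) runs as:

```bash
walklink generate --n 500 --m-attach 4 --triad-prob 0.3 --seed 7 --out g.tsv
walklink evaluate --graph g.tsv --methods qw-a,qw-l,crw,l3,pa,cn,aa,spm \
    --removals 50 --reps 5 --seed 3 --out results/
```

which writes per-repetition AuPR/AuROC values (`metrics.json`) and a
mean ± std summary table (`summary.tsv`).

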