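"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: scipy's Pade matrix exponential,
per-pair loops and explicit set arithmetic, sharing no code with the package
paths under test.
"""

import math

import numpy as np
import scipy.linalg

from walklink.graph import Graph, adjacency, laplacian


def bf_crw_matrix(graph: Graph, t: float) -> np.ndarray:
    return scipy.linalg.expm(-t * laplacian(graph).astype(float))


def bf_qw_matrix(graph: Graph, t: float, hamiltonian: str) -> np.ndarray:
    h = adjacency(graph) if hamiltonian == "adjacency" else laplacian(graph)
    u = scipy.linalg.expm(-1j * t * h.astype(complex))
    return np.abs(u) ** 2


def bf_walk_score(graph: Graph, p: np.ndarray, pair) -> float:
    """Degree-scaled pair score / self-edge score from an explicit propagator."""
    u, v = pair
    a = adjacency(graph)
    k = a.sum(axis=1)
    iu, iv = graph.index_of(u), graph.index_of(v)
    if iu != iv:
        return float(p[iu, iv] * (k[iu] + k[iv]))
    return 0.5 * sum(p[iu, j] for j in range(graph.n) if a[iu, j] == 1)


def bf_l3(graph: Graph, pair) -> float:
    """Triple loop over degree-normalised 3-paths, self-edges excluded."""
    x, y = pair
    if x == y:
        return 0.0
    a = adjacency(graph).astype(float)
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    ix, iy = graph.index_of(x), graph.index_of(y)
    total = 0.0
    for u in range(graph.n):
        for v in range(graph.n):
            if a[ix, u] and a[u, v] and a[v, iy]:
                total += 1.0 / math.sqrt(k[u] * k[v])
    return total


def bf_cn(graph: Graph, pair) -> float:
    u, v = pair
    if u == v:
        return 0.0
    return float(len(set(graph.neighbors(u)) & set(graph.neighbors(v))))


def bf_aa(graph: Graph, pair) -> float:
    u, v = pair
    if u == v:
        return 0.0
    a = adjacency(graph)
    k = a.sum(axis=1)
    return sum(
        1.0 / math.log(k[graph.index_of(z)])
        for z in set(graph.neighbors(u)) & set(graph.neighbors(v))
    )


def bf_pa(graph: Graph, pair) -> float:
    a = adjacency(graph)
    k = a.sum(axis=1)
    u, v = pair
    return float(k[graph.index_of(u)] * k[graph.index_of(v)])


def bf_auroc(pos, neg) -> float:
    """Exhaustive pairwise comparisons with half-credit ties."""
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def bf_aupr(pos, neg) -> float:
    """Average precision by exhaustive enumeration of distinct thresholds."""
    pos, neg = list(pos), list(neg)
    thresholds = sorted(set(pos) | set(neg), reverse=True)
    area = 0.0
    prev_recall = 0.0
    for thr in thresholds:
        tp = sum(1 for s in pos if s >= thr)
        fp = sum(1 for s in neg if s >= thr)
        recall = tp / len(pos)
        precision = tp / (tp + fp)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def bf_spm_reconstruct(a_reduced: np.ndarray, delta_a: np.ndarray) -> np.ndarray:
    """First-order eigen-perturbation written out eigenvalue by eigenvalue."""
    w, v = np.linalg.eigh(a_reduced)
    n = len(w)
    corr = np.array(
        [float(v[:, k] @ delta_a @ v[:, k]) / float(v[:, k] @ v[:, k]) for k in range(n)]
    )
    # group numerically coincident eigenvalues and average their corrections
    groups = []
    current = [0]
    for k in range(1, n):
        if w[k] - w[k - 1] <= 1e-10:
            current.append(k)
        else:
            groups.append(current)
            current = [k]
    groups.append(current)
    out = np.zeros((n, n))
    for grp in groups:
        mean_corr = float(np.mean([corr[k] for k in grp]))
        for k in grp:
            out += (w[k] + mean_corr) * np.outer(v[:, k], v[:, k])
    return out
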