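"""Comparison link predictors: L3, preferential attachment, common neighbours,
Adamic-Adar, and the structural perturbation method (SPM).

L3 counts degree-normalised paths of length three,

    S(x, y) = sum_{u,v} A_xu A_uv A_vy / sqrt(k_u k_v),

the interaction-specific predictor of Kovacs et al.; self-edges are excluded
from path enumeration and from the normalising degrees.  PA multiplies the
endpoint degrees; CN counts common neighbours; AA down-weights common
neighbours by 1/log(k).  SPM removes a random fraction of edges, applies
first-order eigenvalue perturbation theory to the reduced adjacency matrix
(eigenvectors held fixed), and scores non-edges by the reconstructed matrix
entries averaged over several runs.

None of these heuristics defines a self-edge score except PA (extended
naturally to k_i^2); the others score absent self-pairs as 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .graph import Graph, adjacency, degrees

__all__ = [
    "BaselineSpec",
    "l3_score",
    "pa_score",
    "cn_score",
    "aa_score",
    "l3_matrix",
    "spm_perturbed_matrix",
    "spm_matrix",
    "baseline_scores",
    "BASELINE_METHODS",
]

Pair = tuple

BASELINE_METHODS = ("l3", "pa", "cn", "aa", "spm")


@dataclass(frozen=True)
class BaselineSpec:
    """Configuration for the stochastic SPM baseline."""

    method: str = "spm"
    spm_perturbation_fraction: float = 0.1
    spm_runs: int = 10
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.spm_perturbation_fraction < 1.0):
            raise ValueError(
                "spm_perturbation_fraction must lie in (0, 1), got "
                f"{self.spm_perturbation_fraction}"
            )
        if self.spm_runs < 1:
            raise ValueError("spm_runs must be a positive integer")


def _simple_adjacency(graph: Graph) -> np.ndarray:
    a = adjacency(graph).astype(float)
    np.fill_diagonal(a, 0.0)
    return a


def _check_candidate(graph: Graph, pair: Pair) -> tuple[int, int]:
    u, v = pair
    if graph.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is an existing edge, not a candidate")
    return graph.index_of(u), graph.index_of(v)


def l3_matrix(graph: Graph) -> np.ndarray:
    """Matrix of degree-normalised length-3 path counts (self-edges excluded)."""
    a0 = _simple_adjacency(graph)
    k0 = a0.sum(axis=1)
    with np.errstate(divide="ignore"):
        d = np.where(k0 > 0, 1.0 / np.sqrt(k0), 0.0)
    w = a0 * d[:, None] * d[None, :]
    return a0 @ w @ a0


def l3_score(graph: Graph, pair: Pair) -> float:
    iu, iv = _check_candidate(graph, pair)
    if iu == iv:
        return 0.0
    return float(l3_matrix(graph)[iu, iv])


def pa_score(graph: Graph, pair: Pair) -> float:
    """Preferential attachment k_i * k_j; a self-pair scores k_i^2."""
    iu, iv = _check_candidate(graph, pair)
    k = degrees(graph)
    return float(k[iu] * k[iv])


def cn_score(graph: Graph, pair: Pair) -> float:
    iu, iv = _check_candidate(graph, pair)
    if iu == iv:
        return 0.0
    u, v = pair
    return float(len(graph.neighbors(u) & graph.neighbors(v)))


def aa_score(graph: Graph, pair: Pair) -> float:
    """Adamic-Adar: common neighbours weighted by 1/log(degree)."""
    iu, iv = _check_candidate(graph, pair)
    if iu == iv:
        return 0.0
    u, v = pair
    k = degrees(graph)
    total = 0.0
    for z in graph.neighbors(u) & graph.neighbors(v):
        total += 1.0 / math.log(k[graph.index_of(z)])
    return total


# -- structural perturbation method ------------------------------------------


def spm_perturbed_matrix(a_reduced: np.ndarray, delta_a: np.ndarray) -> np.ndarray:
    """First-order eigen-perturbation reconstruction of A = A_R + dA.

    Eigenvectors of A_R are kept; eigenvalues receive the first-order
    correction  dlambda_k = x_k' dA x_k / (x_k' x_k).  Numerically coincident
    eigenvalues (gap < 1e-10) are treated as a degenerate block whose
    corrections are averaged, so the reconstruction does not depend on the
    arbitrary basis LAPACK picks inside the block.
    """
    w, v = np.linalg.eigh(a_reduced)
    corrections = np.einsum("ik,ij,jk->k", v, delta_a, v)
    # average corrections inside degenerate blocks
    out = corrections.copy()
    start = 0
    for i in range(1, len(w) + 1):
        if i == len(w) or w[i] - w[i - 1] > 1e-10:
            out[start:i] = corrections[start:i].mean()
            start = i
    return (v * (w + out)) @ v.T


def spm_matrix(
    graph: Graph,
    spec: BaselineSpec = BaselineSpec(),
    *,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Average perturbed-matrix reconstruction over ``spec.spm_runs`` runs.

    Each run removes a uniformly random fraction of the edges as the
    perturbation set dA, eigendecomposes the remaining adjacency matrix, and
    rebuilds the full matrix with first-order eigenvalue corrections.
    """
    if rng is None:
        rng = np.random.default_rng(spec.rng_seed)
    a = adjacency(graph).astype(float)
    edges = graph.edges
    n_perturb = max(1, int(spec.spm_perturbation_fraction * len(edges)))
    acc = np.zeros_like(a)
    for _ in range(spec.spm_runs):
        chosen = rng.choice(len(edges), size=n_perturb, replace=False)
        delta = np.zeros_like(a)
        for c in chosen:
            u, v = edges[c]
            iu, iv = graph.index_of(u), graph.index_of(v)
            delta[iu, iv] = 1.0
            delta[iv, iu] = 1.0
        acc += spm_perturbed_matrix(a - delta, delta)
    return acc / spec.spm_runs


def baseline_scores(
    graph: Graph,
    method: str,
    candidates: Sequence[Pair],
    *,
    spec: BaselineSpec | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Vectorised baseline scores for a candidate list."""
    method = method.lower()
    if method not in BASELINE_METHODS:
        raise ValueError(f"unknown baseline {method!r}; expected one of {BASELINE_METHODS}")
    for pair in candidates:
        _check_candidate(graph, pair)
    idx_i = np.array([graph.index_of(u) for u, _ in candidates], dtype=np.intp)
    idx_j = np.array([graph.index_of(v) for _, v in candidates], dtype=np.intp)
    self_mask = idx_i == idx_j
    k = degrees(graph).astype(float)
    if method == "pa":
        return k[idx_i] * k[idx_j]
    if method == "l3":
        s = l3_matrix(graph)[idx_i, idx_j]
    elif method == "cn":
        a0 = _simple_adjacency(graph)
        s = (a0 @ a0)[idx_i, idx_j]
    elif method == "aa":
        a0 = _simple_adjacency(graph)
        with np.errstate(divide="ignore"):
            invlog = np.where(k > 1, 1.0 / np.log(np.maximum(k, 2.0)), 0.0)
        s = (a0 @ (invlog[:, None] * a0))[idx_i, idx_j]
    else:  # spm
        mat = spm_matrix(graph, spec or BaselineSpec(), rng=rng)
        s = mat[idx_i, idx_j]
    return np.where(self_mask, 0.0, s)
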