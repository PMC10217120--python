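"""Walk-based link-prediction scores and candidate ranking.

For a non-adjacent pair of distinct nodes i != j the score is

    S(i, j; t) = P_ij(t) * (k_i + k_j),

the walk transition probability scaled by the endpoint degrees (a
preferential-attachment-style weighting).  For an absent self-edge the score
is half the total probability of finding the walker among the node's
neighbours,

    S(i, i; t) = 1/2 * sum_{u in N(i)} P_iu(t).

The walk duration defaults to a small multiple of the inverse average degree,
t = c / <k>, the timescale on which a classical walker first leaves a typical
node.  Both <k> and the degrees k_i are taken from the graph actually being
scored (after any edge removal): the predictor only sees the reduced graph.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .graph import Graph, adjacency, degrees
from .walks import TransitionMatrix, WalkSpec, transition

__all__ = [
    "average_degree",
    "default_time",
    "nonedge_candidates",
    "score_pair",
    "walk_scores",
    "rank_candidates",
]

Pair = tuple


def average_degree(graph: Graph) -> float:
    """Mean degree <k> = mean of the adjacency row sums."""
    return float(degrees(graph).mean())


def default_time(graph: Graph, c: float) -> float:
    """Walk duration t = c / <k> on the graph being scored."""
    if c < 0:
        raise ValueError(f"time multiple must be nonnegative, got {c}")
    if graph.m == 0:
        raise ValueError("default_time is undefined on an edgeless graph")
    return c / average_degree(graph)


def nonedge_candidates(graph: Graph, *, include_self: bool = True) -> list[Pair]:
    """All unordered non-edges, optionally including absent self-pairs.

    Pairs are returned in node-index order: (i, i) [if requested] interleaved
    with (i, j), j > i, for each row i — a deterministic enumeration.
    """
    nodes = graph.nodes
    out: list[Pair] = []
    for a, u in enumerate(nodes):
        if include_self and not graph.has_edge(u, u):
            out.append((u, u))
        for v in nodes[a + 1 :]:
            if not graph.has_edge(u, v):
                out.append((u, v))
    return out


def _validate_candidates(graph: Graph, candidates: Iterable[Pair]) -> None:
    for u, v in candidates:
        if graph.has_edge(u, v):
            raise ValueError(f"candidate ({u!r}, {v!r}) is an existing edge")


def score_pair(
    p: TransitionMatrix,
    k: np.ndarray,
    pair: Pair,
    graph: Graph,
) -> float:
    """Score a single non-edge from a precomputed propagator.

    ``k`` is the degree vector of ``graph`` in the same node order as ``p``.
    """
    u, v = pair
    if graph.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is an existing edge, not a candidate")
    iu, iv = graph.index_of(u), graph.index_of(v)
    if iu != iv:
        return float(p.matrix[iu, iv] * (k[iu] + k[iv]))
    # Self-pair: 1/2 sum over neighbours; empty neighbourhood scores 0.
    nbrs = [graph.index_of(w) for w in graph.neighbors(u)]
    if not nbrs:
        return 0.0
    return float(0.5 * p.matrix[iu, nbrs].sum())


def walk_scores(
    graph: Graph,
    spec: WalkSpec,
    candidates: Sequence[Pair],
    *,
    p: TransitionMatrix | None = None,
) -> np.ndarray:
    """Vectorised scores for a candidate list (propagator computed once)."""
    _validate_candidates(graph, candidates)
    if p is None:
        p = transition(graph, spec)
    k = degrees(graph)
    a = adjacency(graph)
    idx_i = np.fromiter(
        (graph.index_of(u) for u, _ in candidates), dtype=np.intp, count=len(candidates)
    )
    idx_j = np.fromiter(
        (graph.index_of(v) for _, v in candidates), dtype=np.intp, count=len(candidates)
    )
    scores = p.matrix[idx_i, idx_j] * (k[idx_i] + k[idx_j])
    self_mask = idx_i == idx_j
    if np.any(self_mask):
        # 1/2 sum_{u in N(i)} P_iu = 1/2 row sum of (A * P) at row i
        self_row = 0.5 * (a * p.matrix).sum(axis=1)
        scores = np.where(self_mask, self_row[idx_i], scores)
    return np.asarray(scores, dtype=float)


def rank_candidates(
    graph: Graph,
    spec: WalkSpec,
    candidates: Sequence[Pair] | None = None,
    *,
    include_self: bool = True,
) -> pd.DataFrame:
    """Rank non-edge candidates by descending score.

    When ``candidates`` is omitted every non-edge (including absent
    self-pairs unless ``include_self=False``) is enumerated.  Ties are broken
    by node-index-lexicographic pair order, so rankings are deterministic.

    Returns a DataFrame with columns ``node_i, node_j, score, rank``; the
    walk specification is attached as ``df.attrs["walk_spec"]``.
    """
    if graph.n == 0:
        raise ValueError("cannot rank candidates of an empty graph")
    if candidates is None:
        candidates = nonedge_candidates(graph, include_self=include_self)
    scores = walk_scores(graph, spec, candidates)
    idx_i = np.array([graph.index_of(u) for u, _ in candidates])
    idx_j = np.array([graph.index_of(v) for _, v in candidates])
    order = np.lexsort((idx_j, idx_i, -scores))
    df = pd.DataFrame(
        {
            "node_i": [candidates[o][0] for o in order],
            "node_j": [candidates[o][1] for o in order],
            "score": scores[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )
    df.attrs["walk_spec"] = spec
    return df
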