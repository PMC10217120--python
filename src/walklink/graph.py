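"""Undirected graphs with optional self-edges, and their matrix representations.

The in-memory :class:`Graph` is deliberately small: an ordered node tuple and a
canonical set of unordered edges.  Self-edges ``(i, i)`` are first-class
citizens (in protein interaction networks they represent self-interacting
proteins) and follow the literal matrix conventions used throughout the
package:

* the adjacency matrix is binary with ``A[i, i] = 1`` iff the self-edge exists;
* the degree of a node is the row sum of ``A``, so a self-edge contributes
  exactly 1 (not 2) to its endpoint's degree;
* the Laplacian is ``L = D - A`` with ``D = diag(row sums of A)``; a node whose
  only edge is a self-edge therefore has ``L[i, i] = 0`` and is inert under the
  classical walk.

Summary statistics (density, clustering, assortativity) are computed on the
simple-graph projection with self-edges removed, since they are ill-defined
otherwise; the number of self-edges is reported separately.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Hashable, Iterable, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "EdgeListParseError",
    "load_edge_list",
    "load_graphml",
    "load_graph",
    "write_edge_list",
    "adjacency",
    "degrees",
    "laplacian",
    "NetworkStats",
    "network_stats",
]

NodeId = Hashable


class EdgeListParseError(ValueError):
    """Raised when an edge-list file cannot be parsed."""


class Graph:
    """An undirected, unweighted graph permitting self-edges.

    Parameters
    ----------
    edges:
        Iterable of node pairs.  Duplicate edges (in either orientation) are
        collapsed; ``(u, u)`` denotes a self-edge.
    nodes:
        Optional explicit node order.  Nodes appearing in ``edges`` but not in
        ``nodes`` are appended in first-appearance order.  The node order
        fixes the row/column indexing of every matrix built from the graph.
    """

    __slots__ = ("_nodes", "_edges", "_index", "_adj")

    def __init__(
        self,
        edges: Iterable[tuple[NodeId, NodeId]] = (),
        nodes: Sequence[NodeId] = (),
    ) -> None:
        index: dict[NodeId, int] = {}
        for v in nodes:
            if v not in index:
                index[v] = len(index)
        raw = list(edges)
        for u, v in raw:
            if u not in index:
                index[u] = len(index)
            if v not in index:
                index[v] = len(index)
        canonical: dict[tuple[int, int], tuple[NodeId, NodeId]] = {}
        for u, v in raw:
            iu, iv = index[u], index[v]
            key = (iu, iv) if iu <= iv else (iv, iu)
            canonical.setdefault(key, (u, v) if iu <= iv else (v, u))
        self._nodes: tuple[NodeId, ...] = tuple(index)
        self._index = index
        self._edges: tuple[tuple[NodeId, NodeId], ...] = tuple(
            canonical[k] for k in sorted(canonical)
        )
        adj: dict[NodeId, set[NodeId]] = {v: set() for v in self._nodes}
        for u, v in self._edges:
            adj[u].add(v)
            adj[v].add(u)
        self._adj = adj

    # -- basic accessors ---------------------------------------------------

    @property
    def nodes(self) -> tuple[NodeId, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[tuple[NodeId, NodeId], ...]:
        """Canonical edge tuples, each ordered by node index."""
        return self._edges

    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def m(self) -> int:
        """Edge count; self-edges count once each."""
        return len(self._edges)

    def index_of(self, v: NodeId) -> int:
        return self._index[v]

    def has_node(self, v: NodeId) -> bool:
        return v in self._index

    def has_edge(self, u: NodeId, v: NodeId) -> bool:
        return u in self._adj and v in self._adj[u]

    def neighbors(self, v: NodeId) -> frozenset[NodeId]:
        """Nodes adjacent to ``v`` (including ``v`` itself if a self-edge exists)."""
        return frozenset(self._adj[v])

    def self_edges(self) -> tuple[NodeId, ...]:
        return tuple(u for u, v in self._edges if u == v)

    def remove_edges(self, removed: Iterable[tuple[NodeId, NodeId]]) -> "Graph":
        """New graph on the same node set with ``removed`` edges deleted."""
        drop = set()
        for u, v in removed:
            iu, iv = self._index[u], self._index[v]
            drop.add((iu, iv) if iu <= iv else (iv, iu))
        kept = [
            e
            for e in self._edges
            if (self._index[e[0]], self._index[e[1]]) not in drop
        ]
        return Graph(kept, nodes=self._nodes)

    def __repr__(self) -> str:  # pragma: no cover
        return f"Graph(n={self.n}, m={self.m})"

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Graph):
            return NotImplemented
        return self._nodes == other._nodes and set(self._edges) == set(other._edges)

    def __hash__(self) -> int:
        return hash((self._nodes, frozenset(self._edges)))

    # -- conversions -------------------------------------------------------

    def to_networkx(self, *, simple: bool = False) -> nx.Graph:
        """Export to :class:`networkx.Graph`; ``simple=True`` drops self-edges."""
        g = nx.Graph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(
            e for e in self._edges if not (simple and e[0] == e[1])
        )
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Graph":
        return cls(g.edges(), nodes=list(g.nodes()))


# -- I/O --------------------------------------------------------------------


def load_edge_list(path) -> Graph:
    """Read a two-column whitespace/tab-separated edge list.

    Lines starting with ``#`` and blank lines are ignored.  A row ``u u``
    denotes a self-edge.  Node identifiers are kept as strings in
    first-appearance order.  Extra columns beyond the first two are ignored.
    """
    edges: list[tuple[str, str]] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise EdgeListParseError(
                    f"{path}: line {lineno}: expected at least two columns, "
                    f"got {len(tokens)}: {stripped!r}"
                )
            edges.append((tokens[0], tokens[1]))
    if not edges:
        raise EdgeListParseError(f"{path}: no edges found")
    return Graph(edges)


def load_graphml(path) -> Graph:
    """Read a GraphML file as an undirected graph (document node order kept)."""
    g = nx.read_graphml(path)
    return Graph.from_networkx(nx.Graph(g))


def load_graph(path) -> Graph:
    """Load an edge list or, when the path ends in ``.graphml``, a GraphML file."""
    if str(path).lower().endswith(".graphml"):
        return load_graphml(path)
    return load_edge_list(path)


def write_edge_list(graph: Graph, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for u, v in graph.edges:
            fh.write(f"{u}\t{v}\n")


# -- matrices ----------------------------------------------------------------


def adjacency(graph: Graph) -> np.ndarray:
    """Binary adjacency matrix in the graph's node order; ``A[i,i]=1`` iff self-edge."""
    if graph.n == 0:
        raise ValueError("adjacency of an empty graph is undefined")
    a = np.zeros((graph.n, graph.n), dtype=np.int64)
    for u, v in graph.edges:
        iu, iv = graph.index_of(u), graph.index_of(v)
        a[iu, iv] = 1
        a[iv, iu] = 1
    return a


def degrees(graph: Graph) -> np.ndarray:
    """Per-node degree k_v = sum_j A_vj; a self-edge contributes 1."""
    return adjacency(graph).sum(axis=1)


def laplacian(graph: Graph) -> np.ndarray:
    """Graph Laplacian L = D - A with D = diag(row sums of A); rows sum to 0."""
    a = adjacency(graph)
    return np.diag(a.sum(axis=1)) - a


# -- summary statistics ------------------------------------------------------


@dataclass(frozen=True)
class NetworkStats:
    """Whole-network summary in the style of a link-prediction benchmark table."""

    n_nodes: int
    n_edges: int
    avg_degree: float
    density: float
    avg_clustering: float
    assortativity: float  # NaN when undefined (degenerate degree sequences)
    sip_count: int

    def to_dict(self) -> dict:
        d = {
            "n_nodes": self.n_nodes,
            "n_edges": self.n_edges,
            "avg_degree": self.avg_degree,
            "density": self.density,
            "avg_clustering": self.avg_clustering,
            "assortativity": None
            if math.isnan(self.assortativity)
            else self.assortativity,
            "sip_count": self.sip_count,
        }
        return d


def network_stats(graph: Graph) -> NetworkStats:
    """Node/edge counts, mean degree, density, clustering, assortativity, self-edges.

    Density, clustering and assortativity are evaluated on the simple-graph
    projection (self-edges removed); mean degree uses the full adjacency row
    sums, so self-edges contribute 1 each.
    """
    k = degrees(graph)
    simple = graph.to_networkx(simple=True)
    n = graph.n
    m_ns = simple.number_of_edges()
    density = 2.0 * m_ns / (n * (n - 1)) if n >= 2 else 0.0
    clustering = nx.average_clustering(simple) if m_ns > 0 else 0.0
    assort = float("nan")
    if n >= 2 and m_ns > 0:
        deg = dict(simple.degree())
        xs = [deg[u] for u, v in simple.edges()] + [deg[v] for u, v in simple.edges()]
        ys = [deg[v] for u, v in simple.edges()] + [deg[u] for u, v in simple.edges()]
        sx = np.std(xs)
        if sx > 0:
            assort = float(np.corrcoef(xs, ys)[0, 1])
    return NetworkStats(
        n_nodes=n,
        n_edges=graph.m,
        avg_degree=float(k.mean()) if n else 0.0,
        density=density,
        avg_clustering=float(clustering),
        assortativity=assort,
        sip_count=len(graph.self_edges()),
    )
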