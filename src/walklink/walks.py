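"""Continuous-time classical and quantum walk propagators.

Classical walk (CRW): a Markov process with rate matrix Q = -L, so the
probability transition matrix is P(t) = exp(-tL).  Rows of P sum to one,
and because L is symmetric, P is symmetric too.

Quantum walk (QW): unitary evolution U(t) = exp(-itH) with Hamiltonian H
either the adjacency matrix (QW-A) or the Laplacian (QW-L).  Transition
probabilities are the squared moduli of the amplitudes,
P_ij(t) = |<j| exp(-itH) |i>|^2, which are row-stochastic by unitarity and
symmetric because H is real symmetric.

Both propagators are evaluated through an exact eigendecomposition of the
real-symmetric generator (complex arithmetic only enters through the phase
factors on the eigenvalues).  A scaled-and-squared truncated-Taylor backend
is kept as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import scipy.linalg

from .graph import Graph, adjacency, laplacian

__all__ = [
    "WalkSpec",
    "TransitionMatrix",
    "matrix_exponential",
    "crw_transition",
    "qw_transition",
    "transition",
    "return_probabilities",
    "mean_return_probability",
]

WalkKind = Literal["crw", "qw"]
HamiltonianKind = Literal["adjacency", "laplacian"]


@dataclass(frozen=True)
class WalkSpec:
    """A walk family and its duration.

    ``hamiltonian`` selects the quantum generator and is ignored for the
    classical walk, which always uses the Laplacian (the only probability-
    conserving choice).
    """

    kind: WalkKind
    t: float
    hamiltonian: HamiltonianKind = "adjacency"

    def __post_init__(self) -> None:
        if self.kind not in ("crw", "qw"):
            raise ValueError(f"unknown walk kind {self.kind!r}")
        if self.hamiltonian not in ("adjacency", "laplacian"):
            raise ValueError(f"unknown hamiltonian {self.hamiltonian!r}")
        if not (self.t >= 0):
            raise ValueError(f"walk time must be nonnegative, got {self.t}")

    @property
    def label(self) -> str:
        if self.kind == "crw":
            return "crw"
        return "qw-a" if self.hamiltonian == "adjacency" else "qw-l"


@dataclass(frozen=True)
class TransitionMatrix:
    """Time-t walk probabilities P_ij(t) in a fixed node order."""

    matrix: np.ndarray
    spec: WalkSpec
    node_order: tuple

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


def _taylor_expm(b: np.ndarray, terms: int = 50) -> np.ndarray:
    """Scaling-and-squaring truncated Taylor series; cross-check backend."""
    norm = np.linalg.norm(b, ord=np.inf)
    squarings = max(0, int(math.ceil(math.log2(norm / 0.5)))) if norm > 0.5 else 0
    c = b / (2.0**squarings)
    result = np.eye(b.shape[0], dtype=c.dtype)
    term = np.eye(b.shape[0], dtype=c.dtype)
    for k in range(1, terms + 1):
        term = term @ c / k
        result = result + term
    for _ in range(squarings):
        result = result @ result
    return result


def matrix_exponential(
    m: np.ndarray,
    scale: complex = 1.0,
    backend: Literal["eigh", "taylor"] = "eigh",
) -> np.ndarray:
    """exp(scale * m) for a real-symmetric (or Hermitian) matrix ``m``.

    The default backend diagonalises ``m = V diag(w) V*`` and exponentiates
    the spectrum, which preserves unitarity/stochasticity to rounding error.
    ``backend="taylor"`` uses a 50-term scaled-and-squared Taylor polynomial.
    """
    m = np.asarray(m)
    if not np.all(np.isfinite(m)):
        raise ValueError("matrix has non-finite entries")
    if not np.allclose(m, m.conj().T):
        raise ValueError("matrix must be symmetric/Hermitian")
    if backend == "taylor":
        return _taylor_expm(np.asarray(m, dtype=np.result_type(m.dtype, type(scale)))
                            * scale)
    if backend != "eigh":
        raise ValueError(f"unknown backend {backend!r}")
    w, v = scipy.linalg.eigh(np.asarray(m, dtype=float)
                             if not np.iscomplexobj(m) else m)
    phases = np.exp(scale * w)
    return (v * phases) @ v.conj().T


def crw_transition(graph: Graph, t: float, *, backend: str = "eigh") -> TransitionMatrix:
    """Classical propagator P(t) = exp(-tL); row-stochastic and symmetric."""
    if t < 0:
        raise ValueError(f"walk time must be nonnegative, got {t}")
    lap = laplacian(graph)
    p = matrix_exponential(lap, scale=-t, backend=backend).real
    np.clip(p, 0.0, 1.0, out=p)
    return TransitionMatrix(p, WalkSpec("crw", t, "laplacian"), graph.nodes)


def qw_transition(
    graph: Graph,
    t: float,
    hamiltonian: HamiltonianKind = "adjacency",
    *,
    backend: str = "eigh",
) -> TransitionMatrix:
    """Quantum propagator P_ij(t) = |<j| exp(-itH) |i>|^2 for H = A or L."""
    if t < 0:
        raise ValueError(f"walk time must be nonnegative, got {t}")
    h = adjacency(graph) if hamiltonian == "adjacency" else laplacian(graph)
    u = matrix_exponential(h, scale=-1j * t, backend=backend)
    p = np.abs(u) ** 2
    np.clip(p, 0.0, 1.0, out=p)
    return TransitionMatrix(p, WalkSpec("qw", t, hamiltonian), graph.nodes)


def transition(graph: Graph, spec: WalkSpec, *, backend: str = "eigh") -> TransitionMatrix:
    if spec.kind == "crw":
        return crw_transition(graph, spec.t, backend=backend)
    return qw_transition(graph, spec.t, spec.hamiltonian, backend=backend)


def return_probabilities(p: TransitionMatrix) -> np.ndarray:
    """Per-node return probabilities P_ii(t), a localisation diagnostic."""
    return np.diag(p.matrix).copy()


def mean_return_probability(p: TransitionMatrix) -> float:
    """P_ii(t) averaged over all nodes."""
    return float(np.diag(p.matrix).mean())
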