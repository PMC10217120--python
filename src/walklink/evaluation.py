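"""Edge-removal cross-validation and ranking metrics.

The protocol: remove a fraction P of the edges uniformly at random and keep
them as positive test cases; every non-edge of the ORIGINAL graph (including
absent self-pairs) is a negative; the predictor sees only the reduced graph
and must rank positives above negatives.  Performance is summarised by the
area under the precision-recall curve (AuPR, the primary metric under the
extreme class imbalance of sparse networks) and the area under the ROC curve
(AuROC, the probability that a random positive outscores a random negative,
ties credited one half).

Each (removal fraction, repetition) cell draws its own child seed from the
master seed, so any cell is reproducible in isolation, and within a
repetition all methods see the same split (paired comparison).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .baselines import BASELINE_METHODS, BaselineSpec, baseline_scores
from .graph import Graph
from .scoring import default_time, nonedge_candidates, walk_scores
from .walks import WalkSpec

__all__ = [
    "SplitSpec",
    "Split",
    "make_split",
    "auroc",
    "aupr",
    "WALK_METHODS",
    "score_method",
    "run_benchmark",
    "summarize",
]

Pair = tuple

WALK_METHODS = ("qw-a", "qw-l", "crw")

# custom scorer: f(reduced_graph, candidates, split, rng) -> scores
Scorer = Callable[[Graph, Sequence[Pair], "Split", np.random.Generator], np.ndarray]


@dataclass(frozen=True)
class SplitSpec:
    """Removal fractions, repetition count, and the master seed."""

    fractions: tuple[float, ...] = (0.10, 0.20, 0.30, 0.40, 0.50)
    repetitions: int = 10
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for p in self.fractions:
            if not (0.0 < p < 1.0):
                raise ValueError(f"removal fraction must lie in (0, 1), got {p}")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass(frozen=True)
class Split:
    """One edge-removal experiment: reduced graph, positives, negatives."""

    reduced: Graph
    positives: tuple[Pair, ...]
    negatives: tuple[Pair, ...]
    fraction: float
    seed: int


def child_seed(master: int, *key: int) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    ss = np.random.SeedSequence(master, spawn_key=key)
    return int(ss.generate_state(1)[0] % (2**31))


def make_split(graph: Graph, fraction: float, seed: int) -> Split:
    """Remove ``floor(fraction * m)`` uniformly random edges as positives.

    Self-edges are removable like any other edge.  Negatives are all
    non-edges of the original graph, including absent self-pairs; removed
    positives are therefore never negatives.
    """
    if not (0.0 < fraction < 1.0):
        raise ValueError(f"removal fraction must lie in (0, 1), got {fraction}")
    n_remove = int(fraction * graph.m)
    if n_remove < 1:
        raise ValueError(
            f"fraction {fraction} removes no edges from a graph with m={graph.m}"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(graph.m, size=n_remove, replace=False)
    positives = tuple(graph.edges[c] for c in sorted(chosen))
    reduced = graph.remove_edges(positives)
    negatives = tuple(nonedge_candidates(graph, include_self=True))
    return Split(reduced, positives, negatives, fraction, seed)


def _check_scores(positive_scores, negative_scores) -> tuple[np.ndarray, np.ndarray]:
    pos = np.asarray(positive_scores, dtype=float)
    neg = np.asarray(negative_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")
    return pos, neg


def auroc(positive_scores, negative_scores) -> float:
    """P(random positive outscores random negative), ties credited 1/2."""
    pos, neg = _check_scores(positive_scores, negative_scores)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(roc_auc_score(y, np.concatenate([pos, neg])))


def aupr(positive_scores, negative_scores) -> float:
    """Non-interpolated area under the precision-recall curve.

    Computed as average precision over the descending-score threshold sweep;
    tied scores are processed as a single threshold block.
    """
    pos, neg = _check_scores(positive_scores, negative_scores)
    y = np.concatenate([np.ones(pos.size), np.zeros(neg.size)])
    return float(average_precision_score(y, np.concatenate([pos, neg])))


def score_method(
    reduced: Graph,
    method: str | Scorer,
    candidates: Sequence[Pair],
    *,
    time_multiple: float = 2.0,
    walk_time: float | None = None,
    spm_spec: BaselineSpec | None = None,
    split: Split | None = None,
    rng: np.random.Generator | None = None,
    score_self_pairs: bool = True,
) -> np.ndarray:
    """Scores for ``candidates`` on the reduced graph.

    ``method`` is a built-in name ('qw-a', 'qw-l', 'crw', 'l3', 'pa', 'cn',
    'aa', 'spm') or a callable ``f(reduced, candidates, split, rng)``.  Walk
    methods use t = time_multiple / <k> of the reduced graph unless an
    explicit ``walk_time`` is given.  With ``score_self_pairs=False``
    self-pair candidates are scored 0 for every method (the no-self-edge
    ablation).  A method that cannot score a candidate scores it 0; the
    candidate is never dropped.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    if callable(method):
        scores = np.asarray(method(reduced, candidates, split, rng), dtype=float)
    else:
        name = method.lower()
        if name in WALK_METHODS:
            t = walk_time if walk_time is not None else default_time(reduced, time_multiple)
            if name == "crw":
                spec = WalkSpec("crw", t, "laplacian")
            else:
                spec = WalkSpec("qw", t, "adjacency" if name == "qw-a" else "laplacian")
            scores = walk_scores(reduced, spec, candidates)
        elif name in BASELINE_METHODS:
            scores = baseline_scores(reduced, name, candidates, spec=spm_spec, rng=rng)
        else:
            raise ValueError(f"unknown method {method!r}")
    if not score_self_pairs:
        self_mask = np.array([u == v for u, v in candidates])
        scores = np.where(self_mask, 0.0, scores)
    return scores


def run_benchmark(
    graph: Graph,
    methods: Sequence[str] | Mapping[str, str | Scorer],
    split_spec: SplitSpec = SplitSpec(),
    *,
    time_multiple: float = 2.0,
    spm_spec: BaselineSpec | None = None,
    score_self_pairs: bool = True,
) -> pd.DataFrame:
    """Full cross-validation sweep over methods x fractions x repetitions.

    ``methods`` may be a list of built-in names or a mapping of display name
    to built-in name / custom scorer callable.  Returns one row per
    (method, fraction, repetition) with columns ``aupr`` and ``auroc``.
    """
    if not isinstance(methods, Mapping):
        methods = {m: m for m in methods}
    rows = []
    for pi, fraction in enumerate(split_spec.fractions):
        for rep in range(split_spec.repetitions):
            seed = child_seed(split_spec.rng_seed, pi, rep)
            split = make_split(graph, fraction, seed)
            candidates = list(split.positives) + list(split.negatives)
            n_pos = len(split.positives)
            for name, method in methods.items():
                rng = np.random.default_rng(
                    child_seed(seed, zlib.crc32(name.encode()) % 2**16)
                )
                scores = score_method(
                    split.reduced,
                    method,
                    candidates,
                    time_multiple=time_multiple,
                    spm_spec=spm_spec,
                    split=split,
                    rng=rng,
                    score_self_pairs=score_self_pairs,
                )
                rows.append(
                    {
                        "method": name,
                        "fraction": fraction,
                        "repetition": rep,
                        "aupr": aupr(scores[:n_pos], scores[n_pos:]),
                        "auroc": auroc(scores[:n_pos], scores[n_pos:]),
                    }
                )
    return pd.DataFrame(rows)


def summarize(results: pd.DataFrame) -> pd.DataFrame:
    """Per-(method, fraction) means and standard deviations of both metrics."""
    return (
        results.groupby(["method", "fraction"], sort=True)[["aupr", "auroc"]]
        .agg(["mean", "std"])
        .reset_index()
    )
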