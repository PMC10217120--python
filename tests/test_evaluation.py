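import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import bf_aupr, bf_auroc
from walklink.evaluation import (
    SplitSpec,
    aupr,
    auroc,
    make_split,
    run_benchmark,
    score_method,
    summarize,
)
from walklink.graph import Graph
from walklink.synthetic import SyntheticConfig, generate_clustered_scalefree

score_lists = st.lists(
    st.integers(min_value=-5, max_value=5).map(float), min_size=1, max_size=25
)


def _complete_graph(n):
    return Graph([(i, j) for i in range(n) for j in range(i + 1, n)])


class TestMakeSplit:
    def test_removal_count(self):
        g = Graph([(i, i + 1) for i in range(20)])  # m = 20
        split = make_split(g, 0.10, seed=1)
        assert len(split.positives) == 2
        assert split.reduced.m == 18
        assert split.reduced.n == g.n  # isolated nodes kept

    def test_deterministic_under_seed(self):
        g = Graph([(i, i + 1) for i in range(30)])
        a = make_split(g, 0.3, seed=5)
        b = make_split(g, 0.3, seed=5)
        assert a.positives == b.positives
        assert a.reduced == b.reduced

    def test_negatives_from_original_graph(self):
        # complete graph on 5 nodes: the only non-edges are absent self-pairs
        g = _complete_graph(5)
        split = make_split(g, 0.5, seed=2)
        assert set(split.negatives) == {(i, i) for i in range(5)}
        assert not set(split.positives) & set(split.negatives)

    def test_self_edges_removable(self):
        g = Graph([(i, i) for i in range(10)])
        split = make_split(g, 0.5, seed=0)
        assert len(split.positives) == 5
        assert all(u == v for u, v in split.positives)

    def test_too_small_removal_rejected(self):
        g = Graph([(1, 2), (2, 3)])
        with pytest.raises(ValueError):
            make_split(g, 0.1, seed=0)


class TestMetrics:
    def test_perfect_separation(self):
        assert auroc([3, 4], [1, 2]) == 1.0
        assert aupr([3, 4], [1, 2]) == 1.0

    def test_small_examples(self):
        assert auroc([3, 1], [2]) == 0.5
        assert aupr([3], [2, 1]) == 1.0
        assert aupr([2], [3, 1]) == 0.5

    def test_constant_scores_auroc_half(self):
        assert auroc([1.0] * 4, [1.0] * 9) == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auroc([], [1.0])
        with pytest.raises(ValueError):
            aupr([1.0], [])

    @given(score_lists, score_lists)
    @settings(max_examples=80, deadline=None)
    def test_oracle_equivalence(self, pos, neg):
        assert auroc(pos, neg) == pytest.approx(bf_auroc(pos, neg), abs=1e-12)
        assert aupr(pos, neg) == pytest.approx(bf_aupr(pos, neg), abs=1e-12)

    @given(score_lists, score_lists)
    @settings(max_examples=50, deadline=None)
    def test_auroc_complement_and_monotone_invariance(self, pos, neg):
        tie_free = len(set(pos) | set(neg)) == len(pos) + len(neg)
        if tie_free:
            assert auroc(pos, neg) + auroc(neg, pos) == pytest.approx(1.0)
        transform = lambda xs: [np.expm1(0.5 * x) for x in xs]
        assert auroc(pos, neg) == pytest.approx(
            auroc(transform(pos), transform(neg)), abs=1e-12
        )

    def test_aupr_at_least_prevalence_for_random_ranking_on_average(self):
        rng = np.random.default_rng(0)
        vals = [
            aupr(rng.random(20), rng.random(80)) for _ in range(200)
        ]
        assert np.mean(vals) >= 0.2  # prevalence = 20 / 100


@pytest.fixture(scope="module")
def small_graph():
    return generate_clustered_scalefree(SyntheticConfig(60, 3, 0.3, rng_seed=2))


class TestRunBenchmark:
    def test_reproducible(self, small_graph):
        spec = SplitSpec(fractions=(0.2,), repetitions=1, rng_seed=7)
        a = run_benchmark(small_graph, ["crw", "cn"], spec)
        b = run_benchmark(small_graph, ["crw", "cn"], spec)
        assert a.equals(b)

    def test_perfect_oracle_method(self, small_graph):
        def oracle(reduced, candidates, split, rng):
            pos = set(split.positives)
            return np.array([1.0 if c in pos else 0.0 for c in candidates])

        res = run_benchmark(
            small_graph,
            {"oracle": oracle},
            SplitSpec(fractions=(0.1, 0.5), repetitions=2, rng_seed=3),
        )
        assert (res["aupr"] == 1.0).all()
        assert (res["auroc"] == 1.0).all()

    def test_constant_method_auroc_half(self, small_graph):
        constant = lambda reduced, candidates, split, rng: np.ones(len(candidates))
        res = run_benchmark(
            small_graph,
            {"const": constant},
            SplitSpec(fractions=(0.3,), repetitions=1, rng_seed=1),
        )
        assert res["auroc"].iloc[0] == 0.5

    def test_summary_mean_matches_per_repetition_values(self, small_graph):
        spec = SplitSpec(fractions=(0.2,), repetitions=3, rng_seed=0)
        res = run_benchmark(small_graph, ["pa"], spec)
        summ = summarize(res)
        assert summ[("aupr", "mean")].iloc[0] == pytest.approx(res["aupr"].mean())

    def test_no_self_score_mode_zeroes_self_candidates(self, small_graph):
        split = make_split(small_graph, 0.2, seed=4)
        cands = list(split.negatives)
        scores = score_method(
            split.reduced, "pa", cands, split=split, score_self_pairs=False
        )
        self_mask = np.array([u == v for u, v in cands])
        assert np.all(scores[self_mask] == 0.0)
        assert np.any(scores[~self_mask] > 0.0)

    def test_unknown_method_rejected(self, small_graph):
        with pytest.raises(ValueError):
            score_method(small_graph, "katz", [(0, 59)])

    def test_invalid_split_spec(self):
        with pytest.raises(ValueError):
            SplitSpec(fractions=(0.0,))
        with pytest.raises(ValueError):
            SplitSpec(repetitions=0)
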