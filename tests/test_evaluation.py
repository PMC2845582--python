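"""Cross-validation plan, PR analysis, extrapolation, Wilcoxon dominance."""

import itertools

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.metrics import average_precision_score

from pairpred import (
    ExtrapolationContext,
    auc_pr,
    compare_methods,
    extrapolate_precision,
    grid_search,
    make_cv_plan,
    pr_curve,
    transitive_reduction,
)
from pairpred.evaluation import (
    DEFAULT_C_PLUS_GRID,
    DEFAULT_RATIO_GRID,
    _wilcoxon_exact,
)


class TestCVPlan:
    def test_folds_partition_each_repeat(self):
        y = np.array([1] * 25 + [-1] * 75)
        plan = make_cv_plan(y, seed=3)
        assert plan.n_splits == 15
        for rep in range(3):
            seen = np.zeros(100, dtype=int)
            for f in range(5):
                seen[plan.assignments[rep] == f] += 1
            assert np.all(seen == 1)

    def test_fold_sizes_balanced_overall_and_per_class(self):
        y = np.array([1] * 23 + [-1] * 71)
        plan = make_cv_plan(y, seed=0)
        for rep in range(3):
            row = plan.assignments[rep]
            sizes = np.bincount(row, minlength=5)
            assert sizes.max() - sizes.min() <= 1
            pos_sizes = np.bincount(row[y == 1], minlength=5)
            assert pos_sizes.max() - pos_sizes.min() <= 1

    def test_different_seeds_differ(self):
        y = np.array([1] * 25 + [-1] * 75)
        a = make_cv_plan(y, seed=1).assignments
        b = make_cv_plan(y, seed=2).assignments
        assert not np.array_equal(a, b)
        np.testing.assert_array_equal(a, make_cv_plan(y, seed=1).assignments)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            make_cv_plan([1, -1, 1, -1], seed=0)
        with pytest.raises(ValueError, match="stratification"):
            make_cv_plan([1] * 3 + [-1] * 20, seed=0)


class TestPRCurve:
    def test_perfect_ranking_auc_one(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, -1, -1])
        assert auc_pr(scores, labels) == pytest.approx(1.0)

    def test_hand_enumeration_example(self):
        # thresholds: P=1,R=1/2; P=1/2,R=1/2; P=2/3,R=1 -> AP=(1+2/3)/2
        scores = np.array([0.9, 0.8, 0.7])
        labels = np.array([1, -1, 1])
        assert auc_pr(scores, labels) == pytest.approx(5.0 / 6.0)

    def test_constant_scores_single_point_prevalence(self, caplog):
        scores = np.zeros(8)
        labels = np.array([1, 1, -1, -1, -1, -1, -1, -1])
        precision, recall, thr = pr_curve(scores, labels)
        assert len(precision) == 1
        assert precision[0] == pytest.approx(0.25)
        assert recall[0] == 1.0
        assert auc_pr((precision, recall, thr)) == pytest.approx(0.25)

    def test_matches_average_precision_on_all_label_arrangements(self):
        # oracle equivalence over every arrangement of 8 labels
        scores = np.array([0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2, 0.1])
        for bits in itertools.product([1, -1], repeat=8):
            y = np.array(bits)
            if len(set(bits)) < 2:
                continue
            assert auc_pr(scores, y) == pytest.approx(
                average_precision_score(y, scores), abs=1e-12
            )

    def test_tied_scores_match_sklearn(self, rng):
        scores = rng.integers(0, 4, size=30).astype(float)
        labels = np.where(rng.random(30) < 0.3, 1, -1)
        labels[0], labels[1] = 1, -1
        assert auc_pr(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12
        )

    def test_reversed_perfect_ranking_hits_bruteforce_floor(self, rng):
        # worst ranking on balanced 10-point data retrieves all negatives
        # first: AP = mean_j j/(n_neg + j); brute-force over all distinct
        # arrangements confirms it is the minimum
        scores = np.arange(10, 0, -1).astype(float)
        floor = np.mean([j / (5 + j) for j in range(1, 6)])
        labels = np.array([1] * 5 + [-1] * 5)
        assert auc_pr(-scores, labels) == pytest.approx(floor)
        worst = min(
            auc_pr(scores, np.array(perm))
            for perm in set(itertools.permutations([1] * 5 + [-1] * 5))
        )
        assert worst == pytest.approx(floor)


class TestGridSearch:
    def test_single_point_grid_returned(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([1] * 10 + [-1] * 10)
        best = grid_search(X @ X.T, y, classifier="svm",
                           c_plus_grid=(2.0,), ratio_grid=(3.0,))
        assert best == {"c_plus": 2.0, "ratio": 3.0}

    def test_default_svm_grid_cardinality(self):
        assert len(DEFAULT_C_PLUS_GRID) * len(DEFAULT_RATIO_GRID) == 51

    def test_infeasible_nn_k_skipped(self, rng, caplog):
        # 7 positives: k=15 infeasible in every inner fold, k=1 feasible
        X = np.vstack([rng.standard_normal((7, 2)) + 3,
                       rng.standard_normal((28, 2)) - 3])
        y = np.array([1] * 7 + [-1] * 28)
        with caplog.at_level("WARNING"):
            best = grid_search(X @ X.T, y, classifier="nn", k_grid=(1, 15),
                               seed=5)
        assert best == {"k": 1}
        assert any("infeasible" in r.message for r in caplog.records)

    def test_empty_grid_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array([1] * 10 + [-1] * 10)
        with pytest.raises(ValueError, match="empty"):
            grid_search(X @ X.T, y, classifier="nn", k_grid=())


class TestExtrapolation:
    def test_fixed_points_and_identity(self):
        ctx = ExtrapolationContext(r=3, v=100, e=50)
        assert extrapolate_precision(1.0, ctx) == pytest.approx(1.0)
        assert extrapolate_precision(0.0, ctx) == pytest.approx(0.0)
        # r' = r: identity
        v, e = 7, 3  # r' = (21-3)/3 = 6
        ctx_eq = ExtrapolationContext(r=6, v=v, e=e)
        for p in (0.1, 0.5, 0.9):
            assert extrapolate_precision(p, ctx_eq) == pytest.approx(p)

    def test_direct_substitution_example(self):
        # p=0.5, r=3, r'=30 -> 1/11; choose v, e with r' = 30: v=9, e=...
        # (v(v-1)/2 - e)/e = 30 -> e = v(v-1)/62; v=63 -> e = 63*62/62/...
        ctx = ExtrapolationContext(r=3, v=63, e=63 * 62 // 62 // 1)
        assert ctx.r_prime == pytest.approx(30.0)
        assert extrapolate_precision(0.5, ctx) == pytest.approx(1.0 / 11.0)

    def test_ratio_fields(self):
        ctx = ExtrapolationContext(r=3, v=6187, e=1392)
        assert ctx.r_prime == pytest.approx(
            (6187 * 6186 / 2 - 1392) / 1392
        )
        with pytest.raises(ValueError, match="positive"):
            ExtrapolationContext(r=3, v=10, e=0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        p1=st.floats(0.0, 1.0, allow_nan=False),
        p2=st.floats(0.0, 1.0, allow_nan=False),
    )
    def test_strictly_monotone(self, p1, p2):
        ctx = ExtrapolationContext(r=3, v=200, e=40)
        lo, hi = min(p1, p2), max(p1, p2)
        a, b = extrapolate_precision(lo, ctx), extrapolate_precision(hi, ctx)
        if lo < hi:
            assert a < b
        else:
            assert a == b


class TestWilcoxon:
    def test_exact_p_for_unanimous_dominance(self):
        d = np.linspace(0.01, 0.15, 15)
        w_plus, p_greater, p_two = _wilcoxon_exact(d)
        assert w_plus == 15 * 16 / 2
        assert p_greater == pytest.approx(2.0**-15)
        assert p_two == pytest.approx(2.0**-14)

    def test_matches_scipy_exact(self, rng):
        for _ in range(20):
            d = rng.standard_normal(12)
            d = d[d != 0]
            _, p_greater, _ = _wilcoxon_exact(d)
            ref = stats.wilcoxon(d, alternative="greater", method="exact",
                                 zero_method="wilcox")
            assert p_greater == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_differences_dropped(self):
        d = np.array([0.0, 0.0, 0.1, 0.2, 0.3])
        w_plus, p_greater, _ = _wilcoxon_exact(d)
        assert w_plus == 6.0  # ranks 1+2+3 of the nonzero values
        assert p_greater == pytest.approx(1.0 / 8.0)

    def test_method_vs_itself_no_edge(self):
        auc = {"A": np.full(15, 0.7), "B": np.full(15, 0.7)}
        G = compare_methods(auc)
        assert G.number_of_edges() == 0

    def test_unanimous_dominance_creates_edge(self, rng):
        base = 0.5 + 0.1 * rng.random(15)
        auc = {"A": base + 0.05, "B": base}
        G = compare_methods(auc)
        assert list(G.edges) == [("A", "B")]
        assert G.edges["A", "B"]["p_one_sided"] == pytest.approx(2.0**-15)

    def test_no_two_cycles(self, rng):
        auc = {m: 0.5 + 0.2 * rng.random(15) for m in "ABCD"}
        G = compare_methods(auc)
        for a, b in G.edges:
            assert not G.has_edge(b, a)

    def test_mismatched_split_counts_rejected(self):
        with pytest.raises(ValueError, match="mismatched"):
            compare_methods({"A": np.ones(15), "B": np.ones(10)})


class TestTransitiveReduction:
    def test_textbook_triangle(self):
        G = nx.DiGraph([("A", "B"), ("B", "C"), ("A", "C")])
        R = transitive_reduction(G)
        assert set(R.edges) == {("A", "B"), ("B", "C")}

    def test_edge_free_graph_unchanged(self):
        G = nx.DiGraph()
        G.add_nodes_from("ABC")
        R = transitive_reduction(G)
        assert set(R.nodes) == set("ABC") and R.number_of_edges() == 0

    def test_preserves_reachability_on_random_dags(self, rng):
        for _ in range(20):
            n = 8
            G = nx.DiGraph()
            G.add_nodes_from(range(n))
            for i in range(n):
                for j in range(i + 1, n):
                    if rng.random() < 0.4:
                        G.add_edge(i, j)
            R = transitive_reduction(G)
            for s in range(n):
                # oracle reachability by BFS on both graphs
                assert nx.descendants(G, s) == nx.descendants(R, s)
            assert R.number_of_edges() <= G.number_of_edges()

    def test_cycle_reported_and_returned_unreduced(self, caplog):
        G = nx.DiGraph([("A", "B"), ("B", "A")])
        with caplog.at_level("WARNING"):
            R = transitive_reduction(G)
        assert set(R.edges) == set(G.edges)
        assert any("cycle" in r.message for r in caplog.records)
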