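"""Edge statistics, suprathreshold components, NBS permutation inference,
and the conjunction (logical-AND) operation."""

import itertools
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from oscinet import (
    DesignSpec,
    conjunction,
    edge_stats,
    make_connectivity_cohort,
    nbs,
    suprathreshold_components,
)
from oscinet.nbs import NbsResult, default_primary_threshold


def _stack_from_edge(edge_vals, n_nodes=5, edge=(0, 1)):
    out = np.zeros((len(edge_vals), n_nodes, n_nodes))
    i, j = edge
    for k, v in enumerate(edge_vals):
        out[k, i, j] = out[k, j, i] = v
    return out


class TestEdgeStats:
    def test_constant_covariate_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            DesignSpec(kind="regression", covariate=np.ones(5))

    def test_perfect_linear_relation_beta_one_t_capped(self):
        stack = _stack_from_edge([0.1, 0.2, 0.3, 0.4, 0.5])
        design = DesignSpec(kind="regression", covariate=np.array([1, 2, 3, 4, 5.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            es = edge_stats(stack, design)
        assert es.beta[0, 1] == pytest.approx(1.0)
        assert es.values[0, 1] >= 1e5  # capped, not infinite

    def test_hand_computed_pearson_beta(self):
        stack = _stack_from_edge([0.1, 0.2, 0.3, 0.4, 0.5])
        design = DesignSpec(kind="regression", covariate=np.array([1, 2, 3, 5, 4.0]))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            es = edge_stats(stack, design)
        assert es.beta[0, 1] == pytest.approx(0.9)

    def test_two_group_t_matches_scipy(self):
        from scipy import stats as st

        rng = np.random.default_rng(0)
        vals = rng.normal(0.3, 0.1, 12)
        stack = _stack_from_edge(vals)
        design = DesignSpec(kind="two_group",
                            group_labels=["a"] * 6 + ["b"] * 6)
        es = edge_stats(stack, design)
        expected = st.ttest_ind(vals[:6], vals[6:], equal_var=True).statistic
        assert es.values[0, 1] == pytest.approx(expected, rel=1e-10)


class TestSuprathresholdComponents:
    def test_no_edge_passes_empty(self):
        comps = suprathreshold_components(np.zeros((4, 4)), threshold=1.0)
        assert comps == []

    def test_known_component_structure_vs_bruteforce(self):
        # kept edges {(1,2),(2,3),(5,6)} -> components of sizes 2 and 1;
        # verified against a brute-force union-find oracle
        n = 8
        vals = np.zeros((n, n))
        for i, j in [(1, 2), (2, 3), (5, 6)]:
            vals[i, j] = vals[j, i] = 5.0
        comps = suprathreshold_components(vals, threshold=2.0)
        sizes = sorted(len(c) for c in comps)
        assert sizes == [1, 2]

        # union-find oracle
        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        kept = [(i, j) for i, j in itertools.combinations(range(n), 2)
                if abs(vals[i, j]) > 2.0]
        for i, j in kept:
            parent[find(i)] = find(j)
        from collections import Counter

        oracle_sizes = sorted(Counter(find(i) for i, _ in kept).values())
        assert sizes == oracle_sizes

    def test_fully_connected_graph_single_component(self):
        n = 4
        vals = np.full((n, n), 3.0)
        np.fill_diagonal(vals, 0)
        comps = suprathreshold_components(vals, threshold=1.0)
        assert len(comps) == 1 and len(comps[0]) == 6

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(hst.lists(
        hst.tuples(hst.integers(0, 7), hst.integers(0, 7)), max_size=14))
    def test_component_sizes_match_union_find_on_random_graphs(self, edges):
        """Component edge counts agree with a union-find oracle for
        arbitrary suprathreshold graphs on 8 nodes."""
        n = 8
        vals = np.zeros((n, n))
        kept = set()
        for i, j in edges:
            if i != j:
                vals[i, j] = vals[j, i] = 5.0
                kept.add((min(i, j), max(i, j)))
        comps = suprathreshold_components(vals, threshold=2.0)
        assert sorted(e for c in comps for e in c) == sorted(kept)

        parent = list(range(n))

        def find(a):
            while parent[a] != a:
                a = parent[a]
            return a

        for i, j in kept:
            parent[find(i)] = find(j)
        from collections import Counter

        oracle = sorted(Counter(find(i) for i, _ in kept).values())
        assert sorted(len(c) for c in comps) == oracle

    @pytest.mark.parametrize("tail, expected", [("positive", 1), ("negative", 1),
                                                ("two_sided", 2)])
    def test_tail_selection(self, tail, expected):
        vals = np.zeros((4, 4))
        vals[0, 1] = vals[1, 0] = 5.0
        vals[2, 3] = vals[3, 2] = -5.0
        comps = suprathreshold_components(vals, threshold=2.0, tail=tail)
        assert len(comps) == expected


class TestNbs:
    def test_nperm_default_is_5000(self):
        d = DesignSpec(kind="two_group", group_labels=["a", "b"])
        assert d.nperm == 5000

    def test_small_nperm_rejected(self):
        with pytest.raises(ValueError, match="nperm"):
            DesignSpec(kind="two_group", group_labels=["a", "b"], nperm=50)

    def test_planted_component_detected(self):
        edges5 = [(0, 1), (1, 2), (2, 3), (3, 4), (1, 3)]
        a, b = make_connectivity_cohort(20, 20, 30, seed=42,
                                        effect_edges=edges5, effect_size=0.3)
        design = DesignSpec(kind="two_group", group_labels=["a"] * 20 + ["b"] * 20,
                            nperm=500, seed=0)
        res = nbs(np.concatenate([a, b]), design)
        sig = res.significant_edges()
        assert len(sig & set(edges5)) >= 4
        assert min(res.component_pvalues) < 0.05

    def test_pvalues_bounded_and_monotone_in_size(self):
        a, b = make_connectivity_cohort(10, 10, 15, seed=3,
                                        effect_edges=[(0, 1), (1, 2)], effect_size=0.4)
        design = DesignSpec(kind="two_group", group_labels=["a"] * 10 + ["b"] * 10,
                            nperm=200, seed=1)
        res = nbs(np.concatenate([a, b]), design)
        for p in res.component_pvalues:
            assert 1 / (design.nperm + 1) <= p <= 1.0
        order = np.argsort(res.component_sizes)[::-1]
        ps = np.array(res.component_pvalues)[order]
        assert np.all(np.diff(ps) >= 0)

    def test_seeded_reproducibility(self):
        a, b = make_connectivity_cohort(8, 8, 10, seed=5)
        stack = np.concatenate([a, b])
        design = DesignSpec(kind="two_group", group_labels=["a"] * 8 + ["b"] * 8,
                            nperm=200, seed=11)
        r1, r2 = nbs(stack, design), nbs(stack, design)
        np.testing.assert_array_equal(r1.null_max_sizes, r2.null_max_sizes)
        assert r1.component_pvalues == r2.component_pvalues

    def test_regression_matches_two_group_on_binary_covariate(self):
        """A 0/1 covariate that relabels group membership recovers the same
        suprathreshold component set at matched thresholds (the t statistics
        of a two-group contrast and a regression on its indicator are
        monotone transforms of each other)."""
        edges = [(0, 1), (1, 2)]
        a, b = make_connectivity_cohort(10, 10, 12, seed=9,
                                        effect_edges=edges, effect_size=0.35)
        stack = np.concatenate([a, b])
        d_group = DesignSpec(kind="two_group", group_labels=["a"] * 10 + ["b"] * 10,
                             nperm=200, seed=2)
        d_reg = DesignSpec(kind="regression",
                           covariate=np.array([1.0] * 10 + [0.0] * 10),
                           nperm=200, seed=2)
        es_g = edge_stats(stack, d_group)
        es_r = edge_stats(stack, d_reg)
        # pooled-variance two-sample t equals the regression t on the indicator
        np.testing.assert_allclose(es_g.values, es_r.values, atol=1e-8)
        thr = default_primary_threshold(d_group)
        cg = suprathreshold_components(es_g, thr)
        cr = suprathreshold_components(es_r, thr)
        assert cg == cr


class TestConjunction:
    def _result(self, comps, pvals, n_nodes=10):
        sizes = [len(c) for c in comps]
        stats = edge_stats(
            make_connectivity_cohort(3, 3, n_nodes, seed=0)[0].repeat(2, axis=0),
            DesignSpec(kind="two_group", group_labels=["a"] * 3 + ["b"] * 3),
        )
        return NbsResult(components=comps, component_sizes=sizes,
                         component_pvalues=pvals, null_max_sizes=np.zeros(100, int),
                         observed_stats=stats, threshold=2.0,
                         node_labels=[f"node{i:02d}" for i in range(n_nodes)],
                         alpha=0.05)

    def test_disjoint_significant_components_empty(self):
        a = self._result([[(1, 2)]], [0.01])
        b = self._result([[(3, 4)]], [0.01])
        assert conjunction([a, b]) == set()

    def test_identical_components_returned(self):
        comp = [(1, 2), (2, 3)]
        a = self._result([comp], [0.02])
        b = self._result([comp], [0.03])
        assert conjunction([a, b]) == set(comp)

    def test_partial_overlap_intersection(self):
        a = self._result([[(1, 2), (2, 3)]], [0.01])
        b = self._result([[(2, 3), (7, 8)]], [0.01])
        assert conjunction([a, b]) == {(2, 3)}

    def test_nonsignificant_components_excluded(self):
        a = self._result([[(1, 2), (2, 3)]], [0.30])
        b = self._result([[(2, 3)]], [0.01])
        assert conjunction([a, b]) == set()

    def test_exhaustive_small_cases_vs_set_oracle(self):
        """Enumerated two-result conjunctions over a small edge universe
        agree with the plain set-intersection oracle."""
        universe = [(0, 1), (1, 2), (2, 3), (4, 5)]
        import itertools as it

        for r in range(len(universe) + 1):
            for sub_a in it.combinations(universe, r):
                for sub_b in it.combinations(universe, 2):
                    a = self._result([list(sub_a)] if sub_a else [], [0.01] if sub_a else [])
                    b = self._result([list(sub_b)], [0.01])
                    assert conjunction([a, b]) == (set(sub_a) & set(sub_b))

    def test_mismatched_labels_rejected(self):
        a = self._result([[(1, 2)]], [0.01], n_nodes=10)
        b = self._result([[(1, 2)]], [0.01], n_nodes=8)
        with pytest.raises(ValueError, match="labels"):
            conjunction([a, b])
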