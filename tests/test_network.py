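"""Similarity indices, permutation null, thresholding and module detection."""
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import networkx as nx

from spacernet.arrays import CrisprArray
from spacernet.network import (
    NullDistribution,
    binary_jaccard,
    build_network,
    detect_modules,
    permutation_null,
    reshuffle_spacers,
    tanimoto,
    threshold_from_null,
    weighted_jaccard,
)

from conftest import REPEAT, random_seq

counts = st.dictionaries(st.sampled_from("abcdefgh"), st.integers(0, 9), max_size=8)


def make_arrays(spacer_lists):
    return [
        CrisprArray(f"iso{i}", [(f"iso{i}_s{j}", s) for j, s in enumerate(seqs)],
                    REPEAT, (1, 1))
        for i, seqs in enumerate(spacer_lists)
    ]


class TestIndices:
    def test_binary_jaccard_examples(self):
        assert binary_jaccard({"a", "b"}, {"a", "b"}) == 1.0
        assert binary_jaccard({"a"}, {"b"}) == 0.0
        assert binary_jaccard({"a", "b", "c"}, {"b", "c", "d"}) == 0.5
        assert binary_jaccard(set(), set()) == 0.0

    def test_weighted_jaccard_examples(self):
        assert weighted_jaccard({"x": 2, "y": 1}, {"x": 2, "y": 1}) == 1.0
        assert weighted_jaccard({"x": 2}, {"y": 3}) == 0.0
        assert weighted_jaccard({"x": 2, "y": 1}, {"x": 1, "y": 1}) == pytest.approx(2 / 3)

    def test_tanimoto_examples(self):
        assert tanimoto({"x": 1, "y": 1}, {"x": 1, "y": 1}) == 1.0
        assert tanimoto({"x": 2}, {"y": 3}) == 0.0
        assert tanimoto({"x": 1, "y": 1}, {"x": 1}) == pytest.approx(0.5)
        with pytest.raises(ValueError):
            tanimoto({}, {})

    @given(counts, counts)
    @settings(deadline=None)
    def test_symmetric_bounded_identity(self, a, b):
        a = {k: v for k, v in a.items() if v}
        b = {k: v for k, v in b.items() if v}
        for index in (weighted_jaccard, binary_jaccard):
            x = index(a, b) if index is weighted_jaccard else index(set(a), set(b))
            y = index(b, a) if index is weighted_jaccard else index(set(b), set(a))
            assert x == pytest.approx(y)
            assert 0.0 <= x <= 1.0
        if a or b:
            assert 0.0 <= tanimoto(a, b) <= 1.0
        if a:
            assert weighted_jaccard(a, a) == 1.0
            assert tanimoto(a, a) == pytest.approx(1.0)


class TestPermutationNull:
    def test_replicates_conserve_counts_and_multiset(self, small_cohort):
        rng = np.random.default_rng(0)
        arrays = small_cohort.arrays
        from spacernet.catalog import canonical

        original = Counter(canonical(s) for a in arrays for s in a.sequences)
        for _ in range(20):
            counters = reshuffle_spacers(arrays, rng)
            assert [sum(c.values()) for c in counters] == [len(a) for a in arrays]
            merged = Counter()
            for c in counters:
                merged += c
            assert merged == original  # global multiset exactly conserved

    def test_two_disjoint_singletons_values_binary(self):
        """Two isolates with one distinct spacer each: any reshuffle that
        produces sharing gives index 1 when both isolates hold the same
        spacer, so pooled values lie in {0, 1}."""
        arrays = make_arrays([["AAAACCCCGGGGTTTTAAAACCCCGGGGTTTT"],
                              ["TTTTGGGGCCCCAAAATTTTGGGGCCCCAAAC"]])
        dist = permutation_null(arrays, n_replicates=200, seed=1)
        assert set(np.unique(dist.values)) <= {0.0, 1.0}

    def test_deterministic_under_seed(self, small_cohort):
        a = permutation_null(small_cohort.arrays, 5, seed=9)
        b = permutation_null(small_cohort.arrays, 5, seed=9)
        assert np.array_equal(a.values, b.values)

    def test_bad_arguments(self, small_cohort):
        with pytest.raises(ValueError):
            permutation_null(small_cohort.arrays[:1], 10)
        with pytest.raises(ValueError):
            permutation_null(small_cohort.arrays, 0)


class TestThreshold:
    def test_all_zero_values(self):
        dist = NullDistribution(np.zeros(100), 1)
        assert threshold_from_null(dist, 95) == 0.0

    def test_nearest_rank_on_grid(self):
        values = np.arange(0.01, 1.005, 0.01)
        dist = NullDistribution(values, 1)
        assert threshold_from_null(dist, 95) == pytest.approx(0.95)

    def test_percentile_100_is_max(self):
        dist = NullDistribution(np.array([0.2, 0.7, 0.4]), 1)
        assert threshold_from_null(dist, 100) == 0.7

    def test_monotone_in_percentile(self):
        rng = np.random.default_rng(3)
        dist = NullDistribution(rng.random(500), 1)
        values = [threshold_from_null(dist, p) for p in range(0, 101, 5)]
        assert values == sorted(values)

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            threshold_from_null(NullDistribution(np.zeros(0), 1), 95)


class TestBuildNetwork:
    def setup_method(self):
        s = [random_seq(np.random.default_rng(i), 32) for i in range(6)]
        # A-B share 2 of 4 clusters (J=0.5); B-C share 1 of 20 (J=0.05)
        self.arrays = make_arrays(
            [[s[0], s[1], s[2]], [s[1], s[2], s[3]],
             [s[3]] + [random_seq(np.random.default_rng(100 + i), 32) for i in range(19)]]
        )

    def test_threshold_zero_connects_all_sharing_pairs(self):
        g = build_network(self.arrays, threshold=0.0)
        assert set(map(frozenset, g.edges)) == {frozenset({"iso0", "iso1"}),
                                                frozenset({"iso1", "iso2"})}

    def test_threshold_above_one_removes_all_edges(self):
        g = build_network(self.arrays, threshold=1.01)
        assert g.number_of_edges() == 0
        assert g.number_of_nodes() == 3  # isolated nodes kept

    def test_intermediate_threshold_keeps_only_strong_edge(self):
        g = build_network(self.arrays, threshold=0.12)
        assert list(map(sorted, g.edges)) == [["iso0", "iso1"]]

    def test_boundary_edge_kept_at_exact_threshold(self):
        g = build_network(self.arrays, threshold=0.5)
        assert g.has_edge("iso0", "iso1")  # jaccard exactly 0.5 -> kept

    def test_raising_threshold_never_adds_edges(self):
        prev = None
        for thr in (0.0, 0.05, 0.12, 0.5, 0.8):
            edges = set(map(frozenset, build_network(self.arrays, threshold=thr).edges))
            if prev is not None:
                assert edges <= prev
            prev = edges


class TestDetectModules:
    @pytest.mark.parametrize("method", ["connected-components", "label-propagation",
                                        "greedy-modularity"])
    def test_two_disjoint_cliques(self, method):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(5))
        part = detect_modules(g, method, seed=1)
        assert part.n_modules == 2
        assert sorted(part.module_sizes.values()) == [4, 5]

    def test_edgeless_graph_all_singletons(self):
        g = nx.empty_graph(7)
        part = detect_modules(g, "greedy-modularity")
        assert part.n_modules == 7
        assert part.n_singletons == 7

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            detect_modules(nx.empty_graph(2), "map-equation")

    def test_partition_covers_all_nodes(self, small_cohort):
        g = build_network(small_cohort.arrays, threshold=0.1)
        part = detect_modules(g)
        assert set(part.assignments) == set(g.nodes)
        assert sum(part.module_sizes.values()) == g.number_of_nodes()
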