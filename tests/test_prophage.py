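"""MAD-based prophage calling, gapless identity, dedup graph and MCL."""
import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from spacernet.prophage import (
    GenomeTargetSummary,
    call_regions,
    dedup_graph,
    lifestyle_flag,
    mad,
    mcl_cluster,
    pairwise_identity,
)
from spacernet.sequences import encode, revcomp

from conftest import mutate, random_seq


def oracle_identity(a, b):
    """Exhaustive all-diagonal gapless scan (both strands of b)."""
    best = (0, 0)
    ea = encode(a)
    for bb in (b, revcomp(b)):
        eb = encode(bb)
        for d in range(-len(bb) + 1, len(a)):
            lo, hi = max(0, d), min(len(a), len(bb) + d)
            if hi <= lo:
                continue
            matches = int((ea[lo:hi] == eb[lo - d : hi - d]).sum())
            if matches > best[0]:
                best = (matches, hi - lo)
    if best[1] == 0:
        return 0.0, 0.0
    return 100.0 * best[0] / best[1], 100.0 * best[1] / min(len(a), len(b))


class TestMad:
    def test_identical_positions_zero(self):
        assert mad([7, 7, 7]) == 0.0

    def test_hand_enumerated_examples(self):
        assert mad([10, 12, 14]) == 2.0          # median 12, |dev| {2,0,2}
        assert mad([1, 2, 3, 4, 100]) == 1.0     # median 3, |dev| {2,1,0,1,97}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad([])

    @given(st.lists(st.floats(-1e6, 1e6), min_size=1, max_size=40),
           st.floats(-1e5, 1e5), st.floats(-50, 50))
    @settings(deadline=None, max_examples=80)
    def test_translation_and_scale(self, xs, shift, scale):
        base = mad(xs)
        assert mad([x + shift for x in xs]) == pytest.approx(base, abs=1e-6)
        assert mad([x * scale for x in xs]) == pytest.approx(abs(scale) * base, rel=1e-9, abs=1e-6)


class TestCallRegions:
    def make_summary(self, positions, length=1_000_000, hit_len=32):
        return GenomeTargetSummary("g", length, list(positions),
                                   [p + hit_len - 1 for p in positions],
                                   [f"h{i}" for i in range(len(positions))])

    def test_region_arithmetic(self):
        positions = list(range(100_000, 150_001, 4545))  # 12 hits, span 100000-150031
        summary = self.make_summary(positions[:12])
        region = call_regions(summary, min_hits=10, flank=25_000)
        assert region is not None
        assert region.start == min(positions[:12]) - 25_000
        assert region.end == max(positions[:12]) + 31 + 25_000

    def test_below_min_hits_returns_none(self):
        summary = self.make_summary(list(range(1000, 10_000, 1000)))  # 9 hits
        assert call_regions(summary, min_hits=10) is None

    def test_clipping_at_origin_and_end(self):
        positions = [5_000 + 100 * i for i in range(10)]
        region = call_regions(self.make_summary(positions, length=25_000))
        assert region.start == 1  # 5000 - 25000 clipped to origin
        assert region.end == 25_000  # 5931 + 25000 clipped to subject length

    def test_negative_flank_rejected(self):
        with pytest.raises(ValueError):
            call_regions(self.make_summary([1] * 10), flank=-1)

    def test_mad_undefined_below_two_hits(self):
        assert self.make_summary([5]).mad is None
        assert self.make_summary([5, 9]).mad == 2.0

    def test_discrimination_clustered_vs_scattered(self):
        """Positions confined to a prophage-sized window have MAD bounded by
        half the window; uniform positions over the genome concentrate near
        genome_length/4."""
        rng = np.random.default_rng(8)
        genome_len, prophage_len = 1_000_000, 40_000
        clustered_mads, scattered_mads = [], []
        for _ in range(100):
            start = rng.integers(1, genome_len - prophage_len)
            inside = rng.integers(start, start + prophage_len, size=12)
            clustered_mads.append(mad(inside))
            scattered_mads.append(mad(rng.integers(1, genome_len, size=12)))
        assert max(clustered_mads) <= prophage_len / 2
        assert min(scattered_mads) > prophage_len / 2  # distributions separate
        assert np.median(scattered_mads) == pytest.approx(genome_len / 4, rel=0.3)


class TestPairwiseIdentity:
    def test_identical_sequences(self, rng):
        a = random_seq(rng, 2000)
        assert pairwise_identity(a, a) == (100.0, 100.0)

    def test_planted_divergence_five_percent(self, rng):
        a = random_seq(rng, 4000)
        b = mutate(rng, a, 200)  # exactly 5% substitutions
        identity, coverage = pairwise_identity(a, b)
        assert identity == pytest.approx(95.0, abs=0.01)
        assert coverage == 100.0

    def test_containment_coverage_relative_to_shorter(self, rng):
        a = random_seq(rng, 3000)
        identity, coverage = pairwise_identity(a, a[:1500])
        assert identity == 100.0
        assert coverage == 100.0

    def test_symmetric(self, rng):
        a, b = random_seq(rng, 1200), random_seq(rng, 900)
        b = a[:600] + b[600:]
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_agrees_with_exhaustive_diagonal_oracle(self, rng):
        for trial in range(5):
            a = random_seq(rng, 800)
            # shifted, mutated, partially overlapping copy
            b = random_seq(rng, 150) + mutate(rng, a[100:700], 12) + random_seq(rng, 100)
            if trial % 2:
                b = revcomp(b)
            assert pairwise_identity(a, b) == pytest.approx(oracle_identity(a, b))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")


class TestDedupGraph:
    def test_duplicates_linked_random_not(self, rng):
        a = random_seq(rng, 1500)
        graph = dedup_graph({"a": a, "dup": mutate(rng, a, 30), "other": random_seq(rng, 1500)})
        assert graph.has_edge("a", "dup")
        assert graph.degree("other") == 0

    def test_triangle_of_near_identical_sequences(self, rng):
        a = random_seq(rng, 1000)
        graph = dedup_graph({"A": a, "B": mutate(rng, a, 20), "C": mutate(rng, a, 20)})
        assert graph.number_of_edges() == 3


class TestMcl:
    def test_barbell_splits_into_two_clusters(self):
        g = nx.barbell_graph(5, 0)  # two K5s joined by a single edge
        clusters = mcl_cluster(g, inflation=2.0)
        assert sorted(sorted(c.members) for c in clusters) == [
            [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]
        ]

    def test_singleton_node(self):
        g = nx.Graph()
        g.add_node("only")
        clusters = mcl_cluster(g)
        assert len(clusters) == 1 and clusters[0].members == ["only"]

    def test_disconnected_components_never_merge(self):
        rng = np.random.default_rng(17)
        for _ in range(25):
            g1 = nx.gnp_random_graph(rng.integers(2, 8), 0.6, seed=int(rng.integers(1e6)))
            g2 = nx.gnp_random_graph(rng.integers(2, 8), 0.6, seed=int(rng.integers(1e6)))
            g = nx.disjoint_union(g1, g2)
            clusters = mcl_cluster(g, inflation=2.0)
            n1 = g1.number_of_nodes()
            for c in clusters:
                sides = {m < n1 for m in c.members}
                assert len(sides) == 1  # no cluster spans both components
            covered = sorted(m for c in clusters for m in c.members)
            assert covered == list(range(g.number_of_nodes()))  # partition

    def test_representative_longest_then_lexicographic(self):
        g = nx.Graph()
        g.add_edge("b", "a")
        g.add_edge("a", "c")
        clusters = mcl_cluster(g, lengths={"a": 10, "b": 30, "c": 30})
        assert clusters[0].representative == "b"  # longest, tie broken to 'b' < 'c'

    def test_inflation_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            mcl_cluster(nx.complete_graph(3), inflation=1.0)


class TestLifestyleFlag:
    @pytest.mark.parametrize(
        "annotations,expected",
        [
            (["phage integrase"], "temperate"),
            (["Serine Recombinase family protein"], "temperate"),
            ([], "virulent-or-unknown"),
            (["major capsid protein"], "virulent-or-unknown"),
        ],
    )
    def test_keyword_heuristic(self, annotations, expected):
        assert lifestyle_flag(annotations) == expected
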