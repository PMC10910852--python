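"""Prophage-region calling from protospacer hit positions, viral sequence
deduplication, and Markov clustering.

A subject whose protospacer hits are tightly clustered (low median absolute
deviation of hit positions) is prophage-like: spacer targets concentrate in
an integrated phage rather than scattering over the chromosome. Subjects
with at least `min_hits` (default 10) targets get one candidate region: the
min-to-max span of the hits extended by a fixed flank (default 25 kb) on
each side, clipped to the subject bounds. Candidate prophages and phage
sequences are then deduplicated at 95% identity over 85% coverage (gapless
k-mer-anchored alignment; coverage relative to the shorter sequence) and
the resulting graph is clustered with a from-scratch Markov clustering
(MCL) implementation.
"""
from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .search import ProtospacerHit
from .sequences import encode, revcomp


def mad(positions: Sequence[float]) -> float:
    """Unscaled median absolute deviation: median(|x - median(x)|).

    No normal-consistency factor is applied; the value is a dispersion
    proxy, not a standard-deviation estimator.
    """
    arr = np.asarray(positions, dtype=float)
    if arr.size == 0:
        raise ValueError("mad of an empty list")
    return float(np.median(np.abs(arr - np.median(arr))))


@dataclass
class GenomeTargetSummary:
    """Per-subject protospacer hit summary driving prophage calling."""

    subject_id: str
    subject_length: int
    hit_positions: list[int]  # 1-based hit starts (unmasked hits only)
    hit_ends: list[int] = field(default_factory=list)
    hit_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.hit_ends:
            self.hit_ends = list(self.hit_positions)

    @property
    def n_hits(self) -> int:
        return len(self.hit_positions)

    @property
    def mad(self) -> float | None:
        """MAD of hit start positions; defined only for >= 2 hits."""
        if self.n_hits < 2:
            return None
        return mad(self.hit_positions)


def summarize_hits(
    subject_id: str,
    subject_length: int,
    hits: Iterable[ProtospacerHit],
) -> GenomeTargetSummary:
    """Build a GenomeTargetSummary from unmasked hits on one subject."""
    kept = [h for h in hits if h.subject_id == subject_id and not h.masked]
    kept.sort(key=lambda h: (h.start, h.strand))
    return GenomeTargetSummary(
        subject_id,
        subject_length,
        [h.start for h in kept],
        [h.end for h in kept],
        [h.spacer_id for h in kept],
    )


@dataclass
class ProphageRegion:
    subject_id: str
    start: int  # 1-based inclusive, clipped to subject bounds
    end: int
    supporting_hits: list[str]
    flank: int = 25_000


def call_regions(
    summary: GenomeTargetSummary, min_hits: int = 10, flank: int = 25_000
) -> ProphageRegion | None:
    """One candidate prophage region per subject, or None below `min_hits`.

    The region spans min hit start − flank to max hit end + flank, clipped
    to [1, subject_length].
    """
    if flank < 0:
        raise ValueError("negative flank")
    if summary.n_hits < min_hits:
        return None
    start = max(1, min(summary.hit_positions) - flank)
    end = min(summary.subject_length, max(summary.hit_ends) + flank)
    return ProphageRegion(summary.subject_id, start, end, list(summary.hit_ids), flank)


def _diagonal_stats(ea: np.ndarray, eb: np.ndarray, d: int) -> tuple[int, int]:
    """(matching columns, aligned columns) of the gapless alignment at
    diagonal offset d (position in a = position in b + d)."""
    a_lo = max(0, d)
    a_hi = min(len(ea), len(eb) + d)
    if a_hi <= a_lo:
        return 0, 0
    seg_a = ea[a_lo:a_hi]
    seg_b = eb[a_lo - d : a_hi - d]
    return int((seg_a == seg_b).sum()), a_hi - a_lo


def pairwise_identity(a: str, b: str, k: int = 15) -> tuple[float, float]:
    """(identity %, coverage %) of the best gapless alignment of two sequences.

    Shared k-mers (either strand of `b`) propose diagonals; each candidate
    diagonal is scored as a full gapless alignment; the diagonal with the
    most matching columns wins. Identity = matching / aligned columns,
    coverage = aligned columns / length of the shorter sequence. Symmetric
    in its arguments.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    k = min(k, len(a), len(b))
    ea = encode(a)
    shorter = min(len(a), len(b))

    best = (0, 0)  # (matches, aligned)
    for bb in (b, revcomp(b)):
        eb = encode(bb)
        index: dict[str, list[int]] = defaultdict(list)
        for i in range(len(a) - k + 1):
            index[a[i : i + k]].append(i)
        diagonals: dict[int, int] = defaultdict(int)
        for j in range(len(bb) - k + 1):
            for i in index.get(bb[j : j + k], ()):
                diagonals[i - j] += 1
        for d, _ in sorted(diagonals.items(), key=lambda kv: -kv[1])[:25]:
            matches, aligned = _diagonal_stats(ea, eb, d)
            if matches > best[0]:
                best = (matches, aligned)
    matches, aligned = best
    if aligned == 0:
        return 0.0, 0.0
    return 100.0 * matches / aligned, 100.0 * aligned / shorter


def dedup_graph(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    min_identity: float = 95.0,
    min_coverage: float = 85.0,
) -> nx.Graph:
    """Deduplication graph: nodes are sequences; an undirected edge joins two
    sequences meeting both the identity and coverage thresholds."""
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        raise ValueError("no sequences")
    graph = nx.Graph()
    for sid, seq in items:
        graph.add_node(sid, length=len(seq))
    for (ida, sa), (idb, sb) in combinations(items, 2):
        identity, coverage = pairwise_identity(sa, sb)
        if identity >= min_identity and coverage >= min_coverage:
            graph.add_edge(ida, idb, identity=identity, coverage=coverage)
    return graph


@dataclass
class SequenceCluster:
    cluster_id: str
    members: list[str]
    representative: str


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-6,
    lengths: Mapping[str, int] | None = None,
) -> list[SequenceCluster]:
    """Markov clustering of an undirected graph.

    The column-stochastic transition matrix (self-loops of weight 1 added)
    is alternately expanded (matrix squaring) and inflated (elementwise
    power then column renormalisation), pruning entries below `tol`, until
    the matrix change drops below `tol` or `max_iter` is reached. Clusters
    are the connected components of the converged matrix's non-zero
    structure, so nodes in different components of the input graph are
    never merged. The representative of each cluster is its longest member
    (node 'length' attribute or `lengths`), ties broken lexicographically.
    """
    if inflation <= 1.0:
        raise ValueError("inflation must exceed 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = sorted(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight=None)
    A += np.eye(len(nodes))
    M = A / A.sum(axis=0, keepdims=True)
    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        inflated[inflated < tol] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0.0] = 1.0
        inflated /= colsum
        change = float(np.abs(inflated - M).max())
        M = inflated
        if change < tol:
            break

    structure = nx.from_numpy_array((M + M.T) > tol)
    size = dict(graph.nodes(data="length"))
    if lengths:
        size.update(lengths)
    clusters = []
    components = sorted(nx.connected_components(structure), key=lambda c: min(c))
    for i, comp in enumerate(sorted(components, key=lambda c: (-len(c), min(c)))):
        members = sorted(nodes[j] for j in comp)
        longest = max(size.get(n) or 0 for n in members)
        rep = min(n for n in members if (size.get(n) or 0) == longest)
        clusters.append(SequenceCluster(f"VC{i:04d}", members, rep))
    return clusters


DEFAULT_TEMPERATE_KEYWORDS = (
    "integrase",
    "serine recombinase",
    "tyrosine recombinase",
    "excisionase",
    "ci repressor",
    "repressor ci",
    "lysogeny",
    "antirepressor",
)


def lifestyle_flag(
    annotations: Iterable[str],
    keywords: Sequence[str] = DEFAULT_TEMPERATE_KEYWORDS,
) -> str:
    """Keyword-based lysogeny heuristic over product annotations.

    Returns 'temperate' when any annotation contains a lysogeny-marker
    keyword (case-insensitive substring), else 'virulent-or-unknown'. This
    is an explicitly heuristic flag, not a lifecycle prediction tool.
    """
    lowered = [a.lower() for a in annotations]
    for product in lowered:
        if any(kw in product for kw in keywords):
            return "temperate"
    return "virulent-or-unknown"
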