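"""Spacer cataloguing: deduplication into clusters, known/new classification
against a reference set, and positional comparisons.

The default clustering policy, ``exact-canonical``, identifies a spacer with
its reverse complement (opposite-strand reads of the same biological spacer
collapse); ``exact`` groups identical strings only. A cluster is *known*
when any member matches a reference spacer exactly, full length, on either
strand; otherwise it is *new*.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .arrays import CrisprArray, relative_positions
from .sequences import revcomp


def canonical(seq: str) -> str:
    """Strand-canonical form: lexicographic min of a sequence and its revcomp."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


@dataclass
class SpacerCluster:
    cluster_id: str
    representative: str  # lexicographically smallest member sequence
    members: list[str]  # spacer ids
    member_sequences: list[str] = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.members)


def cluster_spacers(
    spacers: Sequence[tuple[str, str]], policy: str = "exact-canonical"
) -> list[SpacerCluster]:
    """Partition spacers into clusters of equivalent sequences.

    Returns clusters sorted by decreasing size (ties by representative);
    the sizes always sum to the input count.
    """
    if not spacers:
        raise ValueError("empty spacer list")
    if policy == "exact":
        key = lambda s: s  # noqa: E731
    elif policy == "exact-canonical":
        key = canonical
    else:
        raise ValueError(f"unknown clustering policy {policy!r}")
    groups: dict[str, tuple[list[str], list[str]]] = {}
    for sid, seq in spacers:
        seq = seq.upper()
        ids, seqs = groups.setdefault(key(seq), ([], []))
        ids.append(sid)
        seqs.append(seq)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1][0]), kv[0]))
    return [
        SpacerCluster(f"SC{i:05d}", min(seqs), ids, seqs)
        for i, (_, (ids, seqs)) in enumerate(ordered)
    ]


def classify_known_new(
    clusters: Iterable[SpacerCluster], reference: Iterable[str]
) -> dict[str, str]:
    """Label each cluster 'known' (exact full-length reference match, either
    strand, zero mismatches) or 'new'."""
    ref = {s.upper() for s in reference}
    labels: dict[str, str] = {}
    for cluster in clusters:
        seqs = cluster.member_sequences or [cluster.representative]
        known = any(s in ref or revcomp(s) in ref for s in seqs)
        labels[cluster.cluster_id] = "known" if known else "new"
    return labels


def positional_comparison(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison of relative-position samples.

    Returns (D, p) where D = sup |ECDF_A - ECDF_B| and p comes from the
    asymptotic two-sample KS distribution.
    """
    if not len(group_a) or not len(group_b):
        raise ValueError("both position groups must be non-empty")
    result = stats.ks_2samp(group_a, group_b, method="asymp")
    return float(result.statistic), float(result.pvalue)


def cluster_mean_positions(
    arrays: Sequence[CrisprArray],
    clusters: Sequence[SpacerCluster],
) -> dict[str, float]:
    """Mean relative 5'->3' array position per cluster, unweighted over all
    member occurrences."""
    position_of: dict[str, float] = {}
    for array in arrays:
        for (sid, _), pos in zip(array.spacers, relative_positions(array)):
            position_of[sid] = pos
    means: dict[str, float] = {}
    for cluster in clusters:
        positions = [position_of[sid] for sid in cluster.members if sid in position_of]
        if positions:
            means[cluster.cluster_id] = sum(positions) / len(positions)
    return means


def catalog_table(
    clusters: Sequence[SpacerCluster],
    labels: Mapping[str, str] | None = None,
    mean_positions: Mapping[str, float] | None = None,
):
    """Summary table (pandas DataFrame): cluster_id, size, status, position."""
    import pandas as pd

    rows = []
    for c in clusters:
        rows.append(
            {
                "cluster_id": c.cluster_id,
                "size": c.size,
                "representative": c.representative,
                "status": (labels or {}).get(c.cluster_id, "unclassified"),
                "mean_relative_position": (mean_positions or {}).get(c.cluster_id),
            }
        )
    return pd.DataFrame(rows)
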