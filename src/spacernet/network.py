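"""Spacer-sharing network over isolates, with a permutation-null edge
threshold and pluggable module detection.

Two isolates are linked when they share at least one spacer cluster; the
magnitude of each link is measured by the binary Jaccard index (set
overlap), the weighted Jaccard index (min/max over count vectors) or the
Tanimoto coefficient. The significance threshold for links is calibrated
on random datasets in which the pooled spacer multiset is reshuffled
across isolates, each isolate keeping its original spacer count: pooled
null index values are reduced to an empirical percentile (nearest rank,
default 95th) and every edge below that value is removed. Modules are then
extracted by a community-detection method (greedy modularity by default;
map-equation optimisers can be plugged in externally).
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from itertools import combinations
from typing import Callable, Mapping, Sequence

import networkx as nx
import numpy as np

from .arrays import CrisprArray
from .catalog import canonical


def binary_jaccard(a: set, b: set) -> float:
    """|A∩B| / |A∪B|; 0 when both sets are empty."""
    union = len(a | b)
    if union == 0:
        return 0.0
    return len(a & b) / union


def weighted_jaccard(a: Mapping, b: Mapping) -> float:
    """Σ min(a_i, b_i) / Σ max(a_i, b_i) over count vectors; 0 when both empty."""
    keys = set(a) | set(b)
    if not keys:
        return 0.0
    num = sum(min(a.get(k, 0), b.get(k, 0)) for k in keys)
    den = sum(max(a.get(k, 0), b.get(k, 0)) for k in keys)
    return num / den if den else 0.0


def tanimoto(a: Mapping, b: Mapping) -> float:
    """a·b / (‖a‖² + ‖b‖² − a·b) over count vectors."""
    na = sum(v * v for v in a.values())
    nb = sum(v * v for v in b.values())
    if na == 0 and nb == 0:
        raise ValueError("tanimoto undefined for two zero vectors")
    dot = sum(v * b.get(k, 0) for k, v in a.items())
    return dot / (na + nb - dot)


_INDEX_NAMES = ("binary_jaccard", "weighted_jaccard", "tanimoto")


def _index_value(name: str, ca: Counter, cb: Counter) -> float:
    if name == "binary_jaccard":
        return binary_jaccard(set(ca), set(cb))
    if name == "weighted_jaccard":
        return weighted_jaccard(ca, cb)
    if name == "tanimoto":
        return tanimoto(ca, cb)
    raise ValueError(f"unknown similarity index {name!r}")


def _spacer_counters(
    arrays: Sequence[CrisprArray], key: Callable[[str], str] = canonical
) -> dict[str, Counter]:
    return {a.isolate_id: Counter(key(s) for s in a.sequences) for a in arrays}


@dataclass
class SimilarityEdge:
    isolate_a: str
    isolate_b: str
    shared_count: int
    jaccard_binary: float
    jaccard_weighted: float
    tanimoto: float


def pairwise_edges(arrays: Sequence[CrisprArray]) -> list[SimilarityEdge]:
    """All isolate pairs sharing at least one spacer cluster, with all three
    similarity indices."""
    counters = _spacer_counters(arrays)
    edges = []
    for a, b in combinations(sorted(counters), 2):
        ca, cb = counters[a], counters[b]
        shared = len(set(ca) & set(cb))
        if shared < 1:
            continue
        edges.append(
            SimilarityEdge(
                a,
                b,
                shared,
                binary_jaccard(set(ca), set(cb)),
                weighted_jaccard(ca, cb),
                tanimoto(ca, cb),
            )
        )
    return edges


@dataclass
class NullDistribution:
    values: np.ndarray  # pooled over all sharing pairs and replicates
    n_replicates: int
    index: str = "binary_jaccard"
    percentile: float | None = None
    threshold: float | None = None


def reshuffle_spacers(
    arrays: Sequence[CrisprArray], rng: np.random.Generator
) -> list[Counter]:
    """One null replicate: the pooled spacer multiset randomly redistributed
    among all isolates, each keeping its original spacer count.

    A random permutation of the pool is partitioned by the original
    per-isolate counts; duplicates within an isolate are allowed if drawn.
    Returns one spacer-cluster Counter per isolate, in input order.
    """
    counts = [len(a) for a in arrays]
    pool = np.array([canonical(s) for a in arrays for s in a.sequences], dtype=object)
    shuffled = pool[rng.permutation(len(pool))]
    offsets = np.cumsum([0] + counts)
    return [
        Counter(shuffled[offsets[i] : offsets[i + 1]]) for i in range(len(arrays))
    ]


def permutation_null(
    arrays: Sequence[CrisprArray],
    n_replicates: int = 500,
    index: str = "binary_jaccard",
    seed: int = 0,
) -> NullDistribution:
    """Null similarity distribution under spacer reshuffling.

    Each replicate redistributes spacers with `reshuffle_spacers`; index
    values of every pair sharing at least one spacer are pooled across all
    pairs and replicates.
    """
    if len(arrays) < 2:
        raise ValueError("need at least two isolates")
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    if index not in _INDEX_NAMES:
        raise ValueError(f"unknown similarity index {index!r}")
    rng = np.random.default_rng(seed)
    values: list[float] = []
    for _ in range(n_replicates):
        counters = reshuffle_spacers(arrays, rng)
        sets = [set(c) for c in counters]
        for i, j in combinations(range(len(arrays)), 2):
            if sets[i].isdisjoint(sets[j]):
                continue
            values.append(_index_value(index, counters[i], counters[j]))
    return NullDistribution(np.asarray(values, dtype=float), n_replicates, index)


def threshold_from_null(dist: NullDistribution, percentile: float = 95.0) -> float:
    """Nearest-rank empirical percentile of the pooled null values."""
    if dist.values.size == 0:
        raise ValueError("empty null distribution")
    if not 0.0 <= percentile <= 100.0:
        raise ValueError("percentile must lie in [0, 100]")
    ordered = np.sort(dist.values)
    rank = max(1, int(np.ceil(percentile / 100.0 * ordered.size)))
    threshold = float(ordered[rank - 1])
    dist.percentile = percentile
    dist.threshold = threshold
    return threshold


def build_network(
    arrays: Sequence[CrisprArray],
    index: str = "binary_jaccard",
    threshold: float = 0.0,
) -> nx.Graph:
    """Isolate graph: nodes are all isolates (isolated nodes kept); an edge
    requires at least one shared spacer AND index value >= threshold
    (boundary inclusive)."""
    if index not in _INDEX_NAMES:
        raise ValueError(f"unknown similarity index {index!r}")
    attr = {
        "binary_jaccard": "jaccard_binary",
        "weighted_jaccard": "jaccard_weighted",
        "tanimoto": "tanimoto",
    }[index]
    graph = nx.Graph()
    graph.add_nodes_from(a.isolate_id for a in arrays)
    for edge in pairwise_edges(arrays):
        value = getattr(edge, attr)
        if value >= threshold:
            graph.add_edge(
                edge.isolate_a,
                edge.isolate_b,
                shared_count=edge.shared_count,
                jaccard_binary=edge.jaccard_binary,
                jaccard_weighted=edge.jaccard_weighted,
                tanimoto=edge.tanimoto,
                weight=value,
            )
    return graph


@dataclass
class ModulePartition:
    assignments: dict[str, int]  # isolate id -> module id
    module_sizes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.module_sizes:
            sizes = Counter(self.assignments.values())
            self.module_sizes = dict(sizes)

    @property
    def n_modules(self) -> int:
        return len(self.module_sizes)

    @property
    def n_singletons(self) -> int:
        return sum(1 for s in self.module_sizes.values() if s == 1)


def detect_modules(
    graph: nx.Graph, method: str = "greedy-modularity", seed: int = 0
) -> ModulePartition:
    """Partition the network into modules; isolated nodes become singletons."""
    if method == "connected-components":
        communities = list(nx.connected_components(graph))
    elif method == "label-propagation":
        communities = [
            set(c) for c in nx.community.asyn_lpa_communities(graph, seed=seed)
        ]
    elif method == "greedy-modularity":
        if graph.number_of_edges() == 0:
            communities = [{n} for n in graph.nodes]
        else:
            communities = [
                set(c) for c in nx.community.greedy_modularity_communities(graph)
            ]
    else:
        raise ValueError(f"unknown module-detection method {method!r}")
    communities.sort(key=lambda c: (-len(c), min(c)))
    assignments = {
        node: module for module, members in enumerate(communities) for node in members
    }
    missing = set(graph.nodes) - set(assignments)
    for node in sorted(missing):  # safety: some methods may omit isolated nodes
        assignments[node] = len({m for m in assignments.values()})
    return ModulePartition(assignments)
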