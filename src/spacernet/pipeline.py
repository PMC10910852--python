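"""End-to-end composition of the analysis stages.

extract -> catalog -> network -> search -> prophage -> selftarget, with a
machine-readable summary of per-stage counts. Stages whose inputs are
absent are skipped and report zero counts. A single configured seed feeds
per-stage child seeds by fixed offsets, so identical configuration and
inputs give identical output.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Sequence

from . import catalog, io, network, prophage, search, selftarget
from .arrays import CrisprArray, NoArrayError, extract_spacers
from .config import RunConfig

_NULL_SEED_OFFSET = 1
_MODULE_SEED_OFFSET = 2


def run_pipeline(
    config: RunConfig,
    amplicons: Sequence[tuple[str, str]] | None = None,
    arrays: Sequence[CrisprArray] | None = None,
    subjects: Sequence[tuple[str, str]] | None = None,
    reference_spacers: Sequence[str] | None = None,
    record_roles: Mapping[str, str] | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run the pipeline over in-memory inputs; returns the summary bundle.

    `amplicons` are repeat-containing sequences to extract arrays from
    (skipped records are counted); alternatively pre-built `arrays` may be
    supplied. `subjects` are searched for protospacers and prophage
    regions; when `record_roles` labels subject records as
    chromosome/plasmid, self-targeting detection runs per genome.
    """
    if arrays is None and amplicons is None:
        raise ValueError("either amplicons or arrays must be supplied")
    out = Path(outdir) if outdir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"warnings": []}

    # --- stage: extract -------------------------------------------------
    if arrays is None:
        arrays = []
        failed = 0
        for rec_id, seq in amplicons:
            try:
                arrays.append(
                    extract_spacers(
                        seq,
                        config.repeat,
                        config.repeat_max_mismatches,
                        config.spacer_len_bounds,
                        isolate_id=rec_id,
                    )
                )
            except (NoArrayError, ValueError):
                failed += 1
        summary["n_amplicons_without_array"] = failed
    all_spacers = [(sid, seq) for a in arrays for sid, seq in a.spacers]
    summary["n_isolates"] = len(arrays)
    summary["n_spacers"] = len(all_spacers)
    if out and arrays:
        io.write_spacer_tsv(arrays, out / "spacers.tsv")
        io.write_array_intervals(arrays, out / "arrays.tsv", out / "arrays.bed")

    if not all_spacers:
        summary["warnings"].append("no spacers extracted; downstream stages skipped")
        summary.update(
            n_clusters=0, n_edges=0, n_modules=0, n_hits=0, n_masked_hits=0,
            n_regions=0, n_events=0,
        )
        if out:
            (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
        return summary

    # --- stage: catalog -------------------------------------------------
    clusters = catalog.cluster_spacers(all_spacers, config.cluster_policy)
    summary["n_clusters"] = len(clusters)
    labels = None
    if reference_spacers is not None:
        labels = catalog.classify_known_new(clusters, reference_spacers)
        summary["n_known_clusters"] = sum(1 for v in labels.values() if v == "known")
        summary["n_new_clusters"] = sum(1 for v in labels.values() if v == "new")
    if out:
        means = catalog.cluster_mean_positions(arrays, clusters)
        catalog.catalog_table(clusters, labels, means).to_csv(
            out / "clusters.tsv", sep="\t", index=False
        )

    # --- stage: network -------------------------------------------------
    if len(arrays) >= 2:
        null = network.permutation_null(
            arrays,
            n_replicates=config.null_replicates,
            index=config.similarity_index,
            seed=config.seed + _NULL_SEED_OFFSET,
        )
        threshold = network.threshold_from_null(null, config.null_percentile)
        graph = network.build_network(arrays, config.similarity_index, threshold)
        partition = network.detect_modules(
            graph, config.module_method, seed=config.seed + _MODULE_SEED_OFFSET
        )
        summary["null_threshold"] = threshold
        summary["n_edges"] = graph.number_of_edges()
        summary["n_modules"] = partition.n_modules
        summary["n_singleton_modules"] = partition.n_singletons
        if out:
            io.write_edge_tsv(graph, out / "edges.tsv")
            (out / "modules.json").write_text(
                json.dumps(partition.assignments, indent=1, sort_keys=True)
            )
    else:
        summary.update(n_edges=0, n_modules=len(arrays))
        partition = None

    # --- stage: search + prophage ---------------------------------------
    hits: list[search.ProtospacerHit] = []
    regions: list[prophage.ProphageRegion] = []
    if subjects:
        representatives = [(c.cluster_id, c.representative) for c in clusters]
        hits = list(
            search.scan_collection(
                representatives,
                subjects,
                config.max_mismatches,
                config.repeat,
                config.mask_window,
                config.repeat_max_mismatches,
            )
        )
        lengths = {sid: len(seq) for sid, seq in subjects}
        for sid in lengths:
            summ = prophage.summarize_hits(sid, lengths[sid], hits)
            region = prophage.call_regions(summ, config.min_hits, config.flank)
            if region is not None:
                regions.append(region)
        if out:
            io.write_hits_tsv(hits, out / "hits.tsv")
            io.write_regions(regions, out / "prophage_regions.tsv", out / "prophage_regions.bed")
    summary["n_hits"] = sum(1 for h in hits if not h.masked)
    summary["n_masked_hits"] = sum(1 for h in hits if h.masked)
    summary["n_regions"] = len(regions)

    # --- stage: selftarget ----------------------------------------------
    events: list[selftarget.SelfTargetingEvent] = []
    plasmid_ledger: list[selftarget.SelfTargetingEvent] = []
    if subjects and record_roles:
        records = [
            (sid, seq, record_roles[sid]) for sid, seq in subjects if sid in record_roles
        ]
        if any(role == "chromosome" for _, _, role in records):
            events, plasmid_ledger = selftarget.detect_self_targeting(
                records,
                all_spacers,
                config.repeat,
                config.selftarget_max_mismatches,
                config.repeat_max_mismatches,
            )
            events = selftarget.classify_events(events, regions or None)
        if out:
            io.write_events_tsv(events, out / "self_targeting.tsv")
            io.write_events_tsv(plasmid_ledger, out / "plasmid_only_ledger.tsv")
    summary["n_events"] = len(events)
    summary["n_plasmid_only"] = len(plasmid_ledger)

    if out:
        (out / "summary.json").write_text(json.dumps(summary, indent=1, sort_keys=True))
    return summary
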