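"""File-format helpers: FASTA in/out, coordinate-dialect-aware TSV and BED.

Every human-facing TSV is 1-based inclusive and says so in a header
comment; BED exports are 0-based half-open.
"""
from __future__ import annotations

from typing import Iterable, Iterator, Sequence

import pandas as pd
from Bio import SeqIO

from .arrays import CrisprArray
from .prophage import ProphageRegion
from .search import ProtospacerHit
from .selftarget import SelfTargetingEvent

TSV_COORD_HEADER = "# coordinates: 1-based inclusive\n"


def read_fasta(path) -> Iterator[tuple[str, str]]:
    """Stream (id, sequence) pairs from a FASTA file."""
    for record in SeqIO.parse(str(path), "fasta"):
        yield record.id, str(record.seq).upper()


def write_spacer_tsv(arrays: Sequence[CrisprArray], path) -> None:
    with open(path, "w") as fh:
        fh.write("# spacer inventory; spacer_index is 1-based, 5'->3'\n")
        fh.write("isolate_id\tspacer_index\tspacer_id\tsegment\tsequence\n")
        for array in arrays:
            for i, ((sid, seq), seg) in enumerate(
                zip(array.spacers, array.segment_ids), start=1
            ):
                fh.write(f"{array.isolate_id}\t{i}\t{sid}\t{seg}\t{seq}\n")


def write_array_intervals(arrays: Sequence[CrisprArray], tsv_path, bed_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(TSV_COORD_HEADER)
        fh.write("isolate_id\tstart\tend\tstrand\tn_spacers\n")
        for a in arrays:
            fh.write(
                f"{a.isolate_id}\t{a.source_interval[0]}\t{a.source_interval[1]}"
                f"\t{a.strand}\t{len(a)}\n"
            )
    if bed_path:
        with open(bed_path, "w") as fh:
            for a in arrays:
                fh.write(
                    f"{a.isolate_id}\t{a.source_interval[0] - 1}"
                    f"\t{a.source_interval[1]}\tarray\t0\t{a.strand}\n"
                )


def hits_to_frame(hits: Iterable[ProtospacerHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "spacer_id": h.spacer_id,
                "subject_id": h.subject_id,
                "start": h.start,
                "end": h.end,
                "strand": h.strand,
                "mismatches": h.mismatches,
                "masked": h.masked,
                "mask_reason": h.mask_reason or "",
            }
            for h in hits
        ]
    )


def write_hits_tsv(hits: Iterable[ProtospacerHit], path) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_COORD_HEADER)
        hits_to_frame(hits).to_csv(fh, sep="\t", index=False)


def write_regions(regions: Sequence[ProphageRegion], tsv_path, bed_path=None) -> None:
    with open(tsv_path, "w") as fh:
        fh.write(TSV_COORD_HEADER)
        fh.write("subject_id\tstart\tend\tn_supporting_hits\tflank\n")
        for r in regions:
            fh.write(f"{r.subject_id}\t{r.start}\t{r.end}\t{len(r.supporting_hits)}\t{r.flank}\n")
    if bed_path:
        with open(bed_path, "w") as fh:
            for r in regions:
                fh.write(f"{r.subject_id}\t{r.start - 1}\t{r.end}\tprophage_candidate\n")


def write_events_tsv(events: Sequence[SelfTargetingEvent], path) -> None:
    with open(path, "w") as fh:
        fh.write(TSV_COORD_HEADER)
        fh.write(
            "genome_id\tspacer_id\tarray_record\tarray_start\tarray_end"
            "\ttarget_record\ttarget_start\ttarget_end\ttarget_strand"
            "\ttarget_on_plasmid\toverlaps_prophage\n"
        )
        for e in events:
            ar, as_, ae = e.array_location
            tr, ts, te, strand = e.target_location
            overlap = "unknown" if e.overlaps_prophage is None else str(e.overlaps_prophage)
            fh.write(
                f"{e.genome_id}\t{e.spacer_id}\t{ar}\t{as_}\t{ae}"
                f"\t{tr}\t{ts}\t{te}\t{strand}"
                f"\t{e.target_on_plasmid}\t{overlap}\n"
            )


def write_edge_tsv(graph, path) -> None:
    with open(path, "w") as fh:
        fh.write("isolate_a\tisolate_b\tshared_count\tjaccard_binary\tjaccard_weighted\ttanimoto\n")
        for a, b, data in sorted(graph.edges(data=True)):
            fh.write(
                f"{a}\t{b}\t{data.get('shared_count', '')}"
                f"\t{data.get('jaccard_binary', '')}"
                f"\t{data.get('jaccard_weighted', '')}\t{data.get('tanimoto', '')}\n"
            )
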