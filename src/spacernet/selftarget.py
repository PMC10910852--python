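"""Self-targeting spacer detection.

A self-targeting event is a spacer present both inside a CRISPR array of a
genome and at some other locus of the same genome's chromosome. Array
membership is defined by proximity to the conserved repeat: repeat
occurrences extended by 100 bp each side (overlapping extensions merged)
delimit the array intervals. A spacer whose only extra copy sits on a
plasmid record is NOT an event — the plasmid exception — but is reported
separately for book-keeping. Events can afterwards be classified by
whether the target falls inside a called prophage region.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .arrays import find_repeat_occurrences
from .prophage import ProphageRegion
from .search import find_hits


@dataclass
class SelfTargetingEvent:
    genome_id: str
    spacer_id: str
    array_location: tuple[str, int, int]  # (record id, start, end), 1-based inclusive
    target_location: tuple[str, int, int, str]  # (record id, start, end, strand)
    target_on_plasmid: bool
    overlaps_prophage: bool | None = None  # None = unknown (no region set supplied)


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + 1:
            merged[-1] = (merged[-1][0], max(merged[-1][1], end))
        else:
            merged.append((start, end))
    return merged


def locate_array_intervals(
    records: Mapping[str, str],
    repeat: str,
    max_mismatches: int = 3,
    extension: int = 100,
) -> dict[str, list[tuple[int, int]]]:
    """Array intervals per record: repeat occurrences (both strands) extended
    by `extension` bp each side, clipped to record bounds, merged when the
    extensions overlap."""
    if not repeat:
        raise ValueError("empty repeat")
    intervals: dict[str, list[tuple[int, int]]] = {}
    for rec_id, seq in records.items():
        occ = find_repeat_occurrences(seq, repeat, max_mismatches)
        raw = [
            (max(1, o.start - extension), min(len(seq), o.start + len(repeat) - 1 + extension))
            for o in occ
        ]
        intervals[rec_id] = _merge_intervals(raw)
    return intervals


def _overlaps(start: int, end: int, intervals: Sequence[tuple[int, int]]) -> bool:
    return any(start <= e and end >= s for s, e in intervals)


def detect_self_targeting(
    records: Sequence[tuple[str, str, str]],
    spacers: Sequence[tuple[str, str]],
    repeat: str,
    max_mismatches: int = 0,
    repeat_max_mismatches: int = 3,
    extension: int = 100,
    genome_id: str | None = None,
) -> tuple[list[SelfTargetingEvent], list[SelfTargetingEvent]]:
    """Self-targeting events for one genome.

    `records` are (record_id, sequence, role) with role 'chromosome' or
    'plasmid'; at least one chromosome record is required. A spacer fires
    an event when it occurs inside an array interval (any record) AND at a
    chromosomal locus outside every array interval; matching is exact by
    default (`max_mismatches=0`), the protospacer tolerance being available
    via the flag. Returns (events, plasmid_ledger): spacers whose only
    extra copies are on plasmids are excluded from events and reported in
    the ledger with target_on_plasmid=True.
    """
    roles = {rec_id: role for rec_id, _, role in records}
    if "chromosome" not in roles.values():
        raise ValueError("no chromosome record supplied")
    for role in roles.values():
        if role not in ("chromosome", "plasmid"):
            raise ValueError(f"unknown record role {role!r}")
    seqs = {rec_id: seq.upper() for rec_id, seq, _ in records}
    gid = genome_id or next(r for r, _, role in records if role == "chromosome")
    array_intervals = locate_array_intervals(
        seqs, repeat, repeat_max_mismatches, extension
    )

    events: list[SelfTargetingEvent] = []
    ledger: list[SelfTargetingEvent] = []
    for spacer_id, spacer_seq in spacers:
        resident: tuple[str, int, int] | None = None
        chromosome_targets: list[tuple[str, int, int, str]] = []
        plasmid_targets: list[tuple[str, int, int, str]] = []
        for rec_id, seq in seqs.items():
            for hit in find_hits(
                spacer_seq, seq, max_mismatches, spacer_id=spacer_id, subject_id=rec_id
            ):
                arrays_here = array_intervals.get(rec_id, [])
                if _overlaps(hit.start, hit.end, arrays_here):
                    if resident is None:
                        containing = next(
                            (s, e) for s, e in arrays_here if hit.start <= e and hit.end >= s
                        )
                        resident = (rec_id, *containing)
                elif roles[rec_id] == "chromosome":
                    chromosome_targets.append((rec_id, hit.start, hit.end, hit.strand))
                else:
                    plasmid_targets.append((rec_id, hit.start, hit.end, hit.strand))
        if resident is None:
            continue
        if chromosome_targets:
            for target in chromosome_targets:
                events.append(
                    SelfTargetingEvent(gid, spacer_id, resident, target, False)
                )
        elif plasmid_targets:
            for target in plasmid_targets:
                ledger.append(
                    SelfTargetingEvent(gid, spacer_id, resident, target, True)
                )
    return events, ledger


def classify_events(
    events: Sequence[SelfTargetingEvent],
    prophage_regions: Sequence[ProphageRegion] | None,
) -> list[SelfTargetingEvent]:
    """Set overlaps_prophage on each event; None regions leave it unknown."""
    if prophage_regions is None:
        for event in events:
            event.overlaps_prophage = None
        return list(events)
    by_subject: dict[str, list[tuple[int, int]]] = {}
    for region in prophage_regions:
        by_subject.setdefault(region.subject_id, []).append((region.start, region.end))
    for event in events:
        rec_id, start, end, _ = event.target_location
        event.overlaps_prophage = _overlaps(start, end, by_subject.get(rec_id, []))
    return list(events)
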