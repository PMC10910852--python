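"""Protospacer search: full-length, gapless, mismatch-bounded matching.

A spacer of length L hits a subject wherever some length-L window, on
either strand, lies within `max_mismatches` substitutions (default 4, the
standard tolerance for a 32-nt Type I-E spacer); gaps are never allowed.
The matcher is pigeonhole-seeded: the query is split into
``max_mismatches + 1`` segments, any window within tolerance must contain
at least one segment exactly, so exact segment occurrences enumerate all
candidate windows, which are then verified by direct Hamming count.

Hits adjacent to CRISPR repeats are masked rather than dropped: a hit
within `window` bp (interval gap; overlap counts as 0) of any repeat
occurrence is flagged ``masked`` with reason "repeat-proximal" so that
spacers sitting in arrays are never mistaken for targets.
"""
from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence

from .arrays import RepeatOccurrence, find_repeat_occurrences
from .sequences import revcomp

_VALID = frozenset("ACGT")


@dataclass
class ProtospacerHit:
    spacer_id: str
    subject_id: str
    start: int  # 1-based inclusive, forward strand
    end: int
    strand: str  # '+' spacer matches forward strand, '-' its reverse complement
    mismatches: int
    masked: bool = False
    mask_reason: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _segment_bounds(length: int, pieces: int) -> list[tuple[int, int]]:
    base, extra = divmod(length, pieces)
    bounds = []
    pos = 0
    for i in range(pieces):
        size = base + (1 if i >= pieces - extra else 0)
        if size:
            bounds.append((pos, pos + size))
        pos += size
    return bounds


def _candidate_starts(pattern: str, subject: str, pieces: int) -> set[int]:
    last = len(subject) - len(pattern)
    candidates: set[int] = set()
    for seg_start, seg_end in _segment_bounds(len(pattern), pieces):
        seed = pattern[seg_start:seg_end]
        idx = subject.find(seed)
        while idx != -1:
            w = idx - seg_start
            if 0 <= w <= last:
                candidates.add(w)
            idx = subject.find(seed, idx + 1)
    return candidates


def find_hits(
    spacer: str,
    subject: str,
    max_mismatches: int = 4,
    *,
    spacer_id: str = "spacer",
    subject_id: str = "subject",
) -> list[ProtospacerHit]:
    """All full-length gapless occurrences of `spacer` in `subject`.

    Both strands are searched; hits are reported in forward-strand
    coordinates sorted by (start, strand). A spacer longer than the subject
    yields an empty list with a warning.
    """
    spacer = spacer.upper()
    subject = subject.upper()
    if not spacer:
        raise ValueError("empty spacer")
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be non-negative")
    if set(spacer) - _VALID:
        raise ValueError("spacer must be over the unambiguous alphabet {A,C,G,T}")
    m = len(spacer)
    if m > len(subject):
        warnings.warn("spacer longer than subject; no hits possible", stacklevel=2)
        return []

    hits: list[ProtospacerHit] = []
    for strand, pattern in (("+", spacer), ("-", revcomp(spacer))):
        if m <= max_mismatches:
            candidates: Iterable[int] = range(len(subject) - m + 1)
        else:
            candidates = sorted(_candidate_starts(pattern, subject, max_mismatches + 1))
        for w in candidates:
            window = subject[w : w + m]
            mm = sum(a != b for a, b in zip(pattern, window))
            if mm <= max_mismatches:
                hits.append(
                    ProtospacerHit(spacer_id, subject_id, w + 1, w + m, strand, mm)
                )
    hits.sort(key=lambda h: (h.start, h.strand))
    return hits


def _interval_gap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    """Gap in bp between two closed intervals; 0 when they overlap or abut."""
    if a_start > b_end:
        return a_start - b_end - 1
    if b_start > a_end:
        return b_start - a_end - 1
    return 0


def mask_array_proximal(
    hits: Sequence[ProtospacerHit],
    repeat_occurrences: Sequence[RepeatOccurrence | tuple],
    repeat_length: int,
    window: int = 100,
) -> list[ProtospacerHit]:
    """Flag hits lying within `window` bp of any repeat occurrence.

    "Within" is an interval gap of at most `window` between the hit and the
    repeat occurrence (overlap counts as distance 0). Masked hits are
    retained, flagged, and excluded from downstream counting.
    """
    if window < 0:
        raise ValueError("negative masking window")
    intervals = []
    for occ in repeat_occurrences:
        start = occ.start if isinstance(occ, RepeatOccurrence) else occ[0]
        intervals.append((start, start + repeat_length - 1))
    out = []
    for hit in hits:
        masked = any(
            _interval_gap(hit.start, hit.end, rs, re) <= window for rs, re in intervals
        )
        if masked:
            out.append(dataclasses.replace(hit, masked=True, mask_reason="repeat-proximal"))
        else:
            out.append(dataclasses.replace(hit, masked=False, mask_reason=None))
    return out


def scan_collection(
    spacers: Sequence[tuple[str, str]],
    subjects: Iterable[tuple[str, str]],
    max_mismatches: int = 4,
    repeat: str | None = None,
    mask_window: int = 100,
    repeat_max_mismatches: int = 3,
) -> Iterator[ProtospacerHit]:
    """Stream hits for every (spacer, subject) pair.

    Subjects are processed one at a time (memory independent of collection
    size); when a repeat is supplied, its occurrences on each subject are
    computed once and used to mask repeat-proximal hits.
    """
    for subject_id, subject_seq in subjects:
        occurrences = (
            find_repeat_occurrences(subject_seq, repeat, repeat_max_mismatches)
            if repeat
            else []
        )
        for spacer_id, spacer_seq in spacers:
            hits = find_hits(
                spacer_seq,
                subject_seq,
                max_mismatches,
                spacer_id=spacer_id,
                subject_id=subject_id,
            )
            if repeat:
                hits = mask_array_proximal(hits, occurrences, len(repeat), mask_window)
            yield from hits
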