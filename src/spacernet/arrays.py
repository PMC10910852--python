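"""CRISPR array extraction anchored on a known direct repeat.

An array is a repeat-spacer-...-repeat structure: n spacers interleaved with
n+1 copies of a conserved repeat. Extraction scans a subject for degenerate
repeat copies (Hamming distance up to a tolerance, no indels), chains
non-overlapping occurrences on one strand, and reads the inter-repeat gaps
as spacers. Gaps whose length falls outside the configured bounds (for
example the ~0.5-kb AT-rich insertion that splits some arrays) break the
array into segments; each retained spacer is tagged with its segment index.

Orientation is normalised so that the strand matching the supplied repeat
(not its reverse complement) reads 5'->3'; coordinates in
``source_interval`` always refer to the forward strand of the original
subject.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .sequences import revcomp, sliding_mismatch_counts


class NoArrayError(ValueError):
    """Raised when a subject does not contain a recognisable array."""


@dataclass
class RepeatOccurrence:
    start: int  # 1-based inclusive on the forward strand
    strand: str  # '+' matches the supplied repeat, '-' its reverse complement
    mismatches: int


@dataclass
class CrisprArray:
    """Ordered 5'->3' spacer content of one isolate's array."""

    isolate_id: str
    spacers: list[tuple[str, str]]  # (spacer_id, sequence), leader-proximal first
    repeat: str
    source_interval: tuple[int, int]  # 1-based inclusive, forward strand
    strand: str = "+"
    segment_ids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.spacers:
            raise ValueError("a CRISPR array must contain at least one spacer")
        if not self.segment_ids:
            self.segment_ids = [0] * len(self.spacers)
        for _, seq in self.spacers:
            if seq == self.repeat:
                raise ValueError("spacer identical to the repeat")

    @property
    def sequences(self) -> list[str]:
        return [seq for _, seq in self.spacers]

    def __len__(self) -> int:
        return len(self.spacers)


def find_repeat_occurrences(
    subject: str, repeat: str, max_mismatches: int = 3
) -> list[RepeatOccurrence]:
    """All windows of `subject` within `max_mismatches` of the repeat.

    Both strands are scanned; overlapping occurrences are allowed. Results
    are sorted by start position (then strand).
    """
    if not repeat:
        raise ValueError("empty repeat")
    subject = subject.upper()
    repeat = repeat.upper()
    occurrences: list[RepeatOccurrence] = []
    for strand, pattern in (("+", repeat), ("-", revcomp(repeat))):
        mm = sliding_mismatch_counts(subject, pattern)
        for i in (mm <= max_mismatches).nonzero()[0]:
            occurrences.append(RepeatOccurrence(int(i) + 1, strand, int(mm[i])))
    occurrences.sort(key=lambda o: (o.start, o.strand))
    return occurrences


def _nonoverlapping_chain(
    occurrences: Sequence[RepeatOccurrence], repeat_len: int
) -> list[RepeatOccurrence]:
    chain: list[RepeatOccurrence] = []
    for occ in occurrences:
        if not chain or occ.start > chain[-1].start + repeat_len - 1:
            chain.append(occ)
    return chain


def extract_spacers(
    subject: str,
    repeat: str,
    max_mismatches: int = 3,
    spacer_len_bounds: tuple[int, int] = (20, 50),
    isolate_id: str = "isolate",
) -> CrisprArray:
    """Extract the ordered spacer list from a repeat-anchored array.

    Requires at least two repeat occurrences on one strand; raises
    NoArrayError otherwise, and ValueError when every inter-repeat gap is
    outside ``spacer_len_bounds``.
    """
    subject = subject.upper()
    repeat = repeat.upper()
    lo, hi = spacer_len_bounds
    occurrences = find_repeat_occurrences(subject, repeat, max_mismatches)
    plus = [o for o in occurrences if o.strand == "+"]
    minus = [o for o in occurrences if o.strand == "-"]

    if len(plus) >= 2:
        work, strand = subject, "+"
        chain = _nonoverlapping_chain(plus, len(repeat))
    elif len(minus) >= 2:
        # Normalise orientation: re-scan the reverse complement so the
        # supplied repeat reads 5'->3' in working coordinates.
        work, strand = revcomp(subject), "-"
        flipped = [o for o in find_repeat_occurrences(work, repeat, max_mismatches) if o.strand == "+"]
        chain = _nonoverlapping_chain(flipped, len(repeat))
    else:
        raise NoArrayError("fewer than two repeat occurrences: no array")
    if len(chain) < 2:
        raise NoArrayError("fewer than two non-overlapping repeats: no array")

    spacers: list[tuple[str, str]] = []
    segment_ids: list[int] = []
    segment = 0
    for left, right in zip(chain, chain[1:]):
        gap_start = left.start + len(repeat)  # 1-based
        gap_end = right.start - 1
        gap_len = gap_end - gap_start + 1
        if lo <= gap_len <= hi:
            seq = work[gap_start - 1 : gap_end]
            spacers.append((f"{isolate_id}_s{len(spacers) + 1}", seq))
            segment_ids.append(segment)
        else:
            segment += 1  # out-of-bounds gap splits the array
    if not spacers:
        raise ValueError("all inter-repeat gaps outside spacer length bounds")

    w_start = chain[0].start
    w_end = chain[-1].start + len(repeat) - 1
    if strand == "+":
        interval = (w_start, w_end)
    else:
        n = len(subject)
        interval = (n - w_end + 1, n - w_start + 1)
    return CrisprArray(isolate_id, spacers, repeat, interval, strand, segment_ids)


def relative_positions(array: CrisprArray | int) -> list[float]:
    """Relative 5'->3' position of each spacer on the [0, 1] array axis.

    Spacer i of n maps to (i-1)/(n-1); a single-spacer array maps to 0.5.
    Accepts a CrisprArray or a spacer count.
    """
    n = array if isinstance(array, int) else len(array)
    if n < 1:
        raise ValueError("empty array")
    if n == 1:
        return [0.5]
    return [i / (n - 1) for i in range(n)]
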