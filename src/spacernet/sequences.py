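"""Small nucleotide-sequence utilities shared across the package.

Sequences are plain upper-case Python strings over {A,C,G,T} plus IUPAC
ambiguity codes; every ambiguity code is treated as a mismatch against any
concrete base (conservative matching on low-quality contigs).
"""
from __future__ import annotations

import numpy as np

#: Conserved E. coli CRISPR1 (Type I-E) repeat, 29 nt, written 5'->3'.
ECOLI_CRISPR1_REPEAT = "CGGTTTATCCCCGCTGGCGCGGGGAACAC"

_COMPLEMENT = str.maketrans(
    "ACGTRYSWKMBDHVNacgtryswkmbdhvn",
    "TGCAYRSWMKVHDBNtgcayrswmkvhdbn",
)


def revcomp(seq: str) -> str:
    """Reverse complement, preserving IUPAC ambiguity codes."""
    return seq.translate(_COMPLEMENT)[::-1]


def hamming(a: str, b: str) -> int:
    """Hamming distance between equal-length strings.

    Raises ValueError on unequal lengths; any character difference counts,
    so ambiguity codes mismatch concrete bases.
    """
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def gc_fraction(seq: str) -> float:
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def encode(seq: str) -> np.ndarray:
    """Byte-encode a sequence for vectorised window comparisons."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def sliding_mismatch_counts(subject: str, pattern: str) -> np.ndarray:
    """Hamming distance of `pattern` against every window of `subject`.

    Returns an int array of length ``len(subject) - len(pattern) + 1``
    (empty when the pattern is longer than the subject).
    """
    m = len(pattern)
    if m == 0:
        raise ValueError("empty pattern")
    if m > len(subject):
        return np.zeros(0, dtype=np.int64)
    sub = encode(subject)
    pat = encode(pattern)
    windows = np.lib.stride_tricks.sliding_window_view(sub, m)
    return (windows != pat).sum(axis=1)
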