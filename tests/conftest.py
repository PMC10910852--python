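"""Shared fixtures: small synthetic datasets and brute-force oracles."""
from __future__ import annotations

import numpy as np
import pytest

from spacernet.sequences import ECOLI_CRISPR1_REPEAT, revcomp

REPEAT = ECOLI_CRISPR1_REPEAT
BASES = "ACGT"


def random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


def mutate(rng: np.random.Generator, seq: str, k: int) -> str:
    """Exactly k substitutions at distinct positions."""
    arr = list(seq)
    for pos in rng.choice(len(arr), size=k, replace=False):
        arr[pos] = rng.choice([b for b in BASES if b != arr[pos]])
    return "".join(arr)


def naive_hits(spacer: str, subject: str, max_mismatches: int) -> list[tuple]:
    """Independent brute-force oracle: Hamming-scan every window on both
    strands via vectorised comparison. Returns (start, strand, mismatches)
    tuples, 1-based, sorted like find_hits."""
    out = []
    sub = np.frombuffer(subject.encode(), dtype=np.uint8)
    m = len(spacer)
    if m > len(subject):
        return []
    windows = np.lib.stride_tricks.sliding_window_view(sub, m)
    for strand, pattern in (("+", spacer), ("-", revcomp(spacer))):
        pat = np.frombuffer(pattern.encode(), dtype=np.uint8)
        mm = (windows != pat).sum(axis=1)
        for i in np.nonzero(mm <= max_mismatches)[0]:
            out.append((int(i) + 1, strand, int(mm[i])))
    out.sort(key=lambda t: (t[0], t[1]))
    return out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240114)


@pytest.fixture(scope="session")
def small_cohort():
    from spacernet.synth import sample_cohort

    return sample_cohort(
        30, 3, pool_size=25, spacers_per_isolate=(4, 12), seed=11
    )
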