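"""Synthetic genomes, prophages, CRISPR arrays and cohorts with ground truth.

Every downstream stage of the pipeline is testable against data generated
here: genomes carry implanted prophages and repeat-spacer-repeat arrays at
recorded coordinates, cohorts of isolates draw spacers from latent
module-specific pools sampled out of prophage sequences (with a controlled
number of planted substitutions per spacer), and a fraction of decoy
spacers has no target anywhere. All coordinates in the truth record are
1-based inclusive; identical seeds and parameters give byte-identical
output.

Defaults mirror the study system being emulated: 32-nt spacers, the 29-nt
conserved Type I-E repeat, 2-32 spacers per isolate, a ~40-kb prophage, a
four-substitution matching tolerance.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .arrays import CrisprArray
from .sequences import ECOLI_CRISPR1_REPEAT, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: planted substitutions per non-decoy spacer: P(k) over k = 0..4
DEFAULT_MISMATCH_PROFILE: dict[int, float] = {0: 0.6, 1: 0.2, 2: 0.1, 3: 0.05, 4: 0.05}


@dataclass
class SyntheticTruth:
    """Machine-readable ground truth for one simulated dataset."""

    prophage_intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    # spacer-id -> (subject_id, position, strand, planted_mismatches) or "decoy"
    spacer_origins: dict[str, tuple[str, int, str, int] | str] = field(default_factory=dict)
    module_labels: dict[str, int] = field(default_factory=dict)
    array_locations: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    plasmid_ids: set[str] = field(default_factory=set)

    def to_json(self, path) -> None:
        payload = {
            "prophage_intervals": {k: [list(t) for t in v] for k, v in self.prophage_intervals.items()},
            "spacer_origins": {
                k: (v if isinstance(v, str) else list(v)) for k, v in self.spacer_origins.items()
            },
            "module_labels": self.module_labels,
            "array_locations": {k: [list(t) for t in v] for k, v in self.array_locations.items()},
            "plasmid_ids": sorted(self.plasmid_ids),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            prophage_intervals={k: [tuple(t) for t in v] for k, v in d["prophage_intervals"].items()},
            spacer_origins={
                k: (v if isinstance(v, str) else (v[0], v[1], v[2], v[3]))
                for k, v in d["spacer_origins"].items()
            },
            module_labels={k: int(v) for k, v in d["module_labels"].items()},
            array_locations={k: [tuple(t) for t in v] for k, v in d["array_locations"].items()},
            plasmid_ids=set(d["plasmid_ids"]),
        )


def generate_genome(length: int, gc: float = 0.5, seed: int = 0) -> str:
    """Random nucleotide sequence of `length` bp with expected GC content `gc`."""
    if length < 1:
        raise ValueError("length must be positive")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def _random_seq(rng: np.random.Generator, length: int, gc: float = 0.5) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=length, p=p).tobytes().decode("ascii")


def implant_prophage(
    genome: str, prophage: str, position: int, mode: str = "replace"
) -> tuple[str, tuple[int, int]]:
    """Place a prophage at a 1-based `position`; returns (genome, interval).

    Replacement semantics overwrite the genome slice (coordinates of other
    features stay stable); insertion splices the prophage in.
    """
    if mode not in ("replace", "insert"):
        raise ValueError(f"unknown implant mode {mode!r}")
    if position < 1:
        raise ValueError("position must be >= 1")
    end = position + len(prophage) - 1
    if mode == "replace":
        if end > len(genome):
            raise ValueError("prophage extends beyond genome end")
        new = genome[: position - 1] + prophage + genome[end:]
    else:
        if position > len(genome) + 1:
            raise ValueError("insertion point beyond genome end")
        new = genome[: position - 1] + prophage + genome[position - 1 :]
    return new, (position, end)


def implant_crispr_array(
    genome: str,
    repeat: str,
    spacers: Sequence[str],
    position: int,
    mode: str = "replace",
) -> tuple[str, tuple[int, int]]:
    """Implant repeat + (spacer + repeat) per spacer at `position` (1-based)."""
    if not spacers:
        raise ValueError("at least one spacer required")
    if not repeat:
        raise ValueError("empty repeat")
    locus = repeat + "".join(s + repeat for s in spacers)
    return implant_prophage(genome, locus, position, mode=mode)


def _plant_mismatches(rng: np.random.Generator, seq: str, k: int) -> str:
    """Return `seq` with exactly k substitutions at distinct positions."""
    if k == 0:
        return seq
    arr = bytearray(seq.encode("ascii"))
    for pos in rng.choice(len(arr), size=k, replace=False):
        alternatives = [b for b in b"ACGT" if b != arr[pos]]
        arr[pos] = int(rng.choice(alternatives))
    return arr.decode("ascii")


def _draw_mismatch_count(rng: np.random.Generator, profile: Mapping[int, float]) -> int:
    ks = sorted(profile)
    probs = np.array([profile[k] for k in ks], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(ks, p=probs))


@dataclass
class Cohort:
    """A simulated isolate cohort plus the prophage pools it was drawn from."""

    arrays: list[CrisprArray]
    truth: SyntheticTruth
    prophages: dict[str, str]  # module prophage id -> sequence
    spacer_pool: dict[str, str]  # pool spacer id -> sequence


def sample_cohort(
    n_isolates: int,
    n_modules: int,
    pool_size: int = 60,
    spacers_per_isolate: tuple[int, int] = (2, 32),
    decoy_fraction: float = 0.0,
    mismatch_profile: Mapping[int, float] | None = None,
    seed: int = 0,
    spacer_length: int = 32,
    prophage_length: int = 40_000,
    repeat: str = ECOLI_CRISPR1_REPEAT,
) -> Cohort:
    """Cohort of isolates whose spacers come from module-specific pools.

    Each latent module owns one synthetic prophage; its spacer pool is
    sampled from windows of that prophage (strand chosen at random, planted
    substitutions drawn from `mismatch_profile`) with a `decoy_fraction` of
    random spacers that have no origin. Isolates are assigned to modules
    round-robin and draw a uniform number of spacers (without replacement)
    from their module pool.
    """
    if n_modules > n_isolates:
        raise ValueError("more modules than isolates")
    if n_modules < 1 or pool_size < 1:
        raise ValueError("n_modules and pool_size must be positive")
    lo, hi = spacers_per_isolate
    if not (1 <= lo <= hi <= pool_size):
        raise ValueError("spacers_per_isolate must satisfy 1 <= min <= max <= pool_size")
    if not 0.0 <= decoy_fraction <= 1.0:
        raise ValueError("decoy_fraction must lie in [0, 1]")
    profile = dict(mismatch_profile or DEFAULT_MISMATCH_PROFILE)
    rng = np.random.default_rng(seed)

    truth = SyntheticTruth()
    prophages: dict[str, str] = {}
    spacer_pool: dict[str, str] = {}
    pools: list[list[str]] = []
    for m in range(n_modules):
        pid = f"prophage_m{m}"
        prophages[pid] = _random_seq(rng, prophage_length)
        truth.prophage_intervals[pid] = [(1, prophage_length)]
        pool_ids: list[str] = []
        for j in range(pool_size):
            sid = f"m{m}_p{j}"
            if rng.random() < decoy_fraction:
                spacer_pool[sid] = _random_seq(rng, spacer_length)
                truth.spacer_origins[sid] = "decoy"
            else:
                pos = int(rng.integers(1, prophage_length - spacer_length + 2))
                window = prophages[pid][pos - 1 : pos + spacer_length - 1]
                strand = "+" if rng.random() < 0.5 else "-"
                k = _draw_mismatch_count(rng, profile)
                spacer = window if strand == "+" else revcomp(window)
                spacer_pool[sid] = _plant_mismatches(rng, spacer, k)
                truth.spacer_origins[sid] = (pid, pos, strand, k)
            pool_ids.append(sid)
        pools.append(pool_ids)

    arrays: list[CrisprArray] = []
    for i in range(n_isolates):
        module = i % n_modules
        iso = f"iso{i:04d}"
        truth.module_labels[iso] = module
        n_spacers = int(rng.integers(lo, hi + 1))
        chosen = rng.choice(len(pools[module]), size=n_spacers, replace=False)
        spacers = [
            (f"{iso}:{pools[module][c]}", spacer_pool[pools[module][c]]) for c in chosen
        ]
        locus_len = len(repeat) * (n_spacers + 1) + sum(len(s) for _, s in spacers)
        arrays.append(CrisprArray(iso, spacers, repeat, (1, locus_len), "+"))
    return Cohort(arrays, truth, prophages, spacer_pool)


@dataclass
class GenomeSet:
    """Simulated subject genomes with planted prophages and spacer targets."""

    genomes: dict[str, str]
    spacers: dict[str, list[tuple[str, str]]]  # genome id -> its planted spacers
    truth: SyntheticTruth


def simulate_prophage_genomes(
    n_genomes: int,
    genome_length: int = 300_000,
    prophage_length: int = 40_000,
    spacers_per_genome: tuple[int, int] = (10, 15),
    spacer_length: int = 32,
    mismatch_profile: Mapping[int, float] | None = None,
    decoys_per_genome: int = 0,
    seed: int = 0,
) -> GenomeSet:
    """Genomes with one implanted prophage each and spacers drawn from it.

    Spacer origins in the truth record are genome coordinates inside the
    prophage interval; decoy spacers (random, no origin) can be added to
    exercise specificity.
    """
    if genome_length < prophage_length:
        raise ValueError("genome shorter than prophage")
    profile = dict(mismatch_profile or {0: 1.0})
    rng = np.random.default_rng(seed)
    genomes: dict[str, str] = {}
    spacers: dict[str, list[tuple[str, str]]] = {}
    truth = SyntheticTruth()
    lo, hi = spacers_per_genome
    for g in range(n_genomes):
        gid = f"genome{g:03d}"
        backbone = _random_seq(rng, genome_length)
        prophage = _random_seq(rng, prophage_length)
        pos = int(rng.integers(1, genome_length - prophage_length + 2))
        genome, interval = implant_prophage(backbone, prophage, pos)
        truth.prophage_intervals[gid] = [interval]
        genomes[gid] = genome
        planted: list[tuple[str, str]] = []
        n_sp = int(rng.integers(lo, hi + 1))
        for j in range(n_sp):
            sp_pos = int(rng.integers(interval[0], interval[1] - spacer_length + 2))
            window = genome[sp_pos - 1 : sp_pos + spacer_length - 1]
            strand = "+" if rng.random() < 0.5 else "-"
            k = _draw_mismatch_count(rng, profile)
            spacer = window if strand == "+" else revcomp(window)
            sid = f"{gid}_sp{j}"
            planted.append((sid, _plant_mismatches(rng, spacer, k)))
            truth.spacer_origins[sid] = (gid, sp_pos, strand, k)
        for j in range(decoys_per_genome):
            sid = f"{gid}_decoy{j}"
            planted.append((sid, _random_seq(rng, spacer_length)))
            truth.spacer_origins[sid] = "decoy"
        spacers[gid] = planted
    return GenomeSet(genomes, spacers, truth)


@dataclass
class SelfTargetCase:
    """One genome (chromosome + optional plasmid) built for self-target tests."""

    records: list[tuple[str, str, str]]  # (record_id, sequence, role)
    spacers: list[tuple[str, str]]
    truth: SyntheticTruth
    expected_event_spacers: set[str]  # spacer ids that are true self-target events
    plasmid_only_spacers: set[str]


def simulate_selftarget_case(
    seed: int = 0,
    chromosome_length: int = 120_000,
    prophage_length: int = 20_000,
    plasmid_length: int = 8_000,
    spacer_length: int = 32,
    repeat: str = ECOLI_CRISPR1_REPEAT,
    n_array_only: int = 3,
    n_prophage_targeting: int = 2,
    n_plasmid_targeting: int = 2,
) -> SelfTargetCase:
    """Chromosome with a CRISPR array whose spacers exercise all event classes.

    Array spacers are of three kinds: array-only (no target elsewhere),
    prophage-targeting (an exact copy sits in a distal implanted prophage),
    and plasmid-targeting (exact copy only on the plasmid, the exception
    class that must not be called an event).
    """
    rng = np.random.default_rng(seed)
    truth = SyntheticTruth()
    chrom = _random_seq(rng, chromosome_length)
    gid = "chrom"

    prophage_pos = chromosome_length - prophage_length - 1000
    prophage = _random_seq(rng, prophage_length)
    chrom, pro_interval = implant_prophage(chrom, prophage, prophage_pos)
    truth.prophage_intervals[gid] = [pro_interval]

    plasmid = _random_seq(rng, plasmid_length)

    spacers: list[tuple[str, str]] = []
    expected: set[str] = set()
    plasmid_only: set[str] = set()
    for j in range(n_array_only):
        spacers.append((f"array_only{j}", _random_seq(rng, spacer_length)))
    for j in range(n_prophage_targeting):
        pos = int(rng.integers(pro_interval[0] + 100, pro_interval[1] - spacer_length - 100))
        sid = f"prophage_target{j}"
        spacers.append((sid, chrom[pos - 1 : pos + spacer_length - 1]))
        truth.spacer_origins[sid] = (gid, pos, "+", 0)
        expected.add(sid)
    for j in range(n_plasmid_targeting):
        pos = int(rng.integers(1, plasmid_length - spacer_length + 2))
        sid = f"plasmid_target{j}"
        spacers.append((sid, plasmid[pos - 1 : pos + spacer_length - 1]))
        plasmid_only.add(sid)

    array_pos = 5_000
    chrom, arr_interval = implant_crispr_array(
        chrom, repeat, [s for _, s in spacers], array_pos
    )
    truth.array_locations[gid] = [arr_interval]
    truth.plasmid_ids = {"plasmid1"}
    records = [(gid, chrom, "chromosome"), ("plasmid1", plasmid, "plasmid")]
    return SelfTargetCase(records, spacers, truth, expected, plasmid_only)


def write_fasta(records, path) -> None:
    """Write (id, sequence) pairs as wrapped FASTA (deterministic byte output)."""
    with open(path, "w") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
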