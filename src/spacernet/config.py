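"""Run configuration with the pipeline's standard parameter set.

Defaults are the analysis parameters of the emulated study design: a 29-nt
conserved Type I-E repeat, a four-mismatch full-length gapless protospacer
rule, 100-bp repeat-proximity masking, a 500-replicate permutation null
reduced at its 95th percentile, prophage calling at >= 10 hits with 25-kb
flanks, deduplication at 95% identity over 85% coverage, and MCL inflation
2.0.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import yaml

from .sequences import ECOLI_CRISPR1_REPEAT


@dataclass
class RunConfig:
    repeat: str = ECOLI_CRISPR1_REPEAT
    max_mismatches: int = 4
    mask_window: int = 100
    repeat_max_mismatches: int = 3
    spacer_len_bounds: tuple[int, int] = (20, 50)
    cluster_policy: str = "exact-canonical"
    similarity_index: str = "binary_jaccard"
    null_replicates: int = 500
    null_percentile: float = 95.0
    module_method: str = "greedy-modularity"
    min_hits: int = 10
    flank: int = 25_000
    dedup_identity: float = 95.0
    dedup_coverage: float = 85.0
    inflation: float = 2.0
    selftarget_max_mismatches: int = 0
    seed: int = 0

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        payload["spacer_len_bounds"] = list(self.spacer_len_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "spacer_len_bounds" in payload:
            payload["spacer_len_bounds"] = tuple(payload["spacer_len_bounds"])
        return cls(**payload)
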