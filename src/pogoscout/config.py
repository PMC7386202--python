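"""Pipeline configuration.

Defaults are the mining thresholds of the original pogo survey: TBlastN-style
hits kept at e-value <= 1e-100, top 10 non-overlapping hits per query extracted
with 2 kb flanks, copies counted from alignments > 1000 bp and > 80% identity,
a < 3-copy contamination check, and a 300-aa minimum for an intact transposase.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass


@dataclass
class PipelineConfig:
    evalue_cutoff: float = 1e-100
    flank_bp: int = 2000
    top_hits_per_query: int = 10
    copy_min_len_bp: int = 1000
    copy_min_identity: float = 0.80
    low_copy_threshold: int = 3
    min_tpase_aa: int = 300
    rng_seed: int = 0

    # boundary-stage knobs (calibrated package decisions, not survey values)
    min_tir_len: int = 10
    max_tir_len: int = 1000
    min_tir_identity: float = 0.80
    tsd_max_k: int = 10
    boundary_polish_slack: int = 8

    # contamination flank-mapping (the survey gives no numbers)
    contam_flank_bp: int = 200
    contam_flank_identity: float = 0.90

    def __post_init__(self):
        for name in (
            "evalue_cutoff",
            "flank_bp",
            "top_hits_per_query",
            "copy_min_len_bp",
            "copy_min_identity",
            "low_copy_threshold",
            "min_tpase_aa",
            "min_tir_len",
            "max_tir_len",
            "min_tir_identity",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = json.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
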