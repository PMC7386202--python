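"""Core domain types shared across the annotation pipeline.

Coordinates are 0-based half-open throughout the package; conversion to the
1-based inclusive convention happens only when writing GFF3.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

DNA_ALPHABET = set("ACGTN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomicSequence:
    """A named DNA sequence (contig or assembly scaffold)."""

    id: str
    residues: str
    taxon: Optional[str] = None
    assembly_tag: Optional[str] = None

    def __post_init__(self):
        if not self.residues:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(self.residues.upper()) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-DNA characters: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval [start, end) on a named sequence."""

    seq_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.seq_id}:{self.start}-{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )

    def extract(self, seq: GenomicSequence) -> str:
        """Sequence of this interval, reverse-complemented on the minus strand."""
        if seq.id != self.seq_id:
            raise ValueError(f"interval names {self.seq_id!r}, sequence is {seq.id!r}")
        sub = seq.residues[self.start : self.end]
        return revcomp(sub) if self.strand == "-" else sub


@dataclass(frozen=True)
class HitRecord:
    """One translated-homology hit of a protein query on a genome."""

    query_id: str
    target: Interval
    percent_identity: float  # fraction in [0, 1]
    alignment_length: int
    evalue: float
    bit_score: float

    def __post_init__(self):
        if self.alignment_length < 1:
            raise ValueError("alignment_length must be >= 1")
        if not (0.0 <= self.percent_identity <= 1.0):
            raise ValueError("percent_identity must lie in [0, 1]")
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")


@dataclass
class CandidateLocus:
    """A candidate element locus with its supporting hits and extracted flanks."""

    locus: Interval
    supporting_hits: list = field(default_factory=list)
    flank_left: str = ""
    flank_right: str = ""

    def __post_init__(self):
        if not self.supporting_hits:
            raise ValueError("a candidate locus needs at least one supporting hit")


@dataclass
class CopyNumberReport:
    representative_id: str
    n_copies: int
    flagged_contamination: bool = False

    def __post_init__(self):
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
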