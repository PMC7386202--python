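"""Synthetic genomes, element copies and coding-sequence clades with known truth.

The generator emulates the substrate the mining pipeline assumes: genomes
carrying multi-copy cut-and-paste transposons (TSD + TIR + transposase ORF +
inverted TIR + duplicated TSD), decayed and truncated copies, optional
contaminant contigs, single-copy domesticated-gene orthologs evolving under a
specified dN/dS, and multi-copy low-identity pseudogene-like clades. Every
planted feature is recorded in a TruthSet, the oracle for every later stage.

Default parameters mirror the published survey's regime: elements of
1.2-5.2 kb with transposases of 300-977 aa, a handful of copies per family
per genome (copy numbers in real fungal genomes span 1 to a few hundred),
and domesticated clades of >= 5 species under strong purifying selection.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
from Bio.Seq import Seq
from Bio.Data import CodonTable

from .families import FamilyTemplate, build_templates
from .model import GenomicSequence, Interval, revcomp

# most-frequent codon per amino acid (fixed human-usage-style table; any fixed
# choice works -- determinism is what matters for the truth oracle)
PREFERRED_CODON = {
    "A": "GCC", "C": "TGC", "D": "GAC", "E": "GAG", "F": "TTC",
    "G": "GGC", "H": "CAC", "I": "ATC", "K": "AAG", "L": "CTG",
    "M": "ATG", "N": "AAC", "P": "CCC", "Q": "CAG", "R": "CGG",
    "S": "AGC", "T": "ACC", "V": "GTG", "W": "TGG", "Y": "TAC",
}

STOP_CODONS = {"TAA", "TAG", "TGA"}

# stop codons in all three frames on both strands; placed between the ORF and
# its pads so the planted ORF is recovered exactly by a longest-ORF scan
_STOP_BLOCK = "TTAATTAATTAA"


def back_translate(protein: str) -> str:
    """Deterministic back-translation using the preferred-codon table."""
    try:
        return "".join(PREFERRED_CODON[a] for a in protein)
    except KeyError as exc:
        raise ValueError(f"cannot back-translate residue {exc}")


def translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


@dataclass
class SynthSpec:
    """Parameters of one synthetic dataset."""

    genome_length: int = 150_000
    gc_fraction: float = 0.42
    copies_per_family: int = 5
    substitution_rate: float = 0.02   # per-site decay of non-full copies
    truncation_probability: float = 0.15
    n_species: int = 8
    omega: float = 0.1                # dN/dS of domesticated clades
    divergence: float = 0.2           # expected pairwise substitutions/site
    rng_seed: int = 0
    n_contaminant_contigs: int = 0

    def __post_init__(self):
        for name in ("gc_fraction", "substitution_rate", "truncation_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.omega <= 0:
            raise ValueError("omega must be > 0")
        if self.divergence < 0:
            raise ValueError("divergence must be >= 0")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "SynthSpec":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class TruthCopy:
    """One planted element copy."""

    copy_id: str
    family: str
    locus: Interval
    tir_left: Optional[Interval]
    tir_right: Optional[Interval]
    tsd: str
    orf: Optional[Interval]
    status: str                       # full | decayed | truncated
    element_seq: str = ""
    contaminant: bool = False


@dataclass
class TruthClade:
    """One planted coding-sequence clade."""

    clade_id: str
    kind: str                         # domesticated | pseudogene-like
    family: str
    omega: float
    species: List[str] = field(default_factory=list)
    cds: Dict[str, List[str]] = field(default_factory=dict)  # species -> CDS list


@dataclass
class TruthSet:
    copies: List[TruthCopy] = field(default_factory=list)
    clades: List[TruthClade] = field(default_factory=list)

    def full_copies(self) -> List[TruthCopy]:
        return [c for c in self.copies if c.status == "full"]


def _background(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=n, p=p))


def _substitute_dna(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[("ACGT".index(out[i]) + 1 + rng.integers(3)) % 4]
    return "".join(out)


def _build_element(template: FamilyTemplate, rng: np.random.Generator,
                   gc: float) -> Tuple[str, dict]:
    """Assemble a pristine element: TIR + pad + ORF + pad + inverted TIR.

    Returns the element string and the layout (TIR/ORF offsets within it).
    """
    tir = template.tir_seed
    pad_left = _background(rng, 25, gc) + _STOP_BLOCK
    orf = back_translate(template.tpase_protein) + "TGA"
    pad_right = _STOP_BLOCK + _background(rng, 25, gc)
    element = tir + pad_left + orf + pad_right + revcomp(tir)
    orf_start = len(tir) + len(pad_left)
    layout = {
        "tir_len": len(tir),
        "orf_start": orf_start,
        "orf_end": orf_start + len(orf),
    }
    return element, layout


def _disambiguate_tsd(prev_junction, bg: str) -> str:
    """Keep a planted TSD identifiable as exactly the planted repeat.

    ``bg`` is the background that will sit right of the previous copy's
    second TSD. If the random background happens to extend the duplication
    (e.g. TA flanked by another TA on both sides reads as a genuine TATA
    duplication), the truth label would disagree with the planted sequence;
    the first background base is substituted to break the extension.
    """
    if prev_junction is None or not bg:
        return bg
    left_ctx, tsd = prev_junction
    left_ctx = left_ctx[-12:]
    for cand in (bg[0], "C", "G", "T", "A"):
        candidate = cand + bg[1:]
        repeat = ""
        for k in range(2, min(11, len(left_ctx),
                              len(tsd + candidate)) + 1):
            if left_ctx[-k:] == (tsd + candidate)[:k]:
                repeat = left_ctx[-k:]
        if repeat == tsd:
            return candidate
    return bg


def generate_genome(
    spec: SynthSpec,
    templates: Optional[Dict[str, FamilyTemplate]] = None,
    seq_id: str = "chr1",
) -> Tuple[List[GenomicSequence], TruthSet]:
    """Plant element copies of each template family into a random background.

    Each copy sits between two identical copies of its family's TSD (the
    duplication made at insertion); copies are spaced at least 2 kb apart so
    every copy's flanks are clean background. Decayed copies carry point
    substitutions at ``spec.substitution_rate``; truncated copies lose the
    left TIR and 40% of the ORF.
    """
    templates = templates or build_templates()
    rng = np.random.default_rng(spec.rng_seed)
    fams = sorted(templates)
    plan = [(fam, i) for fam in fams for i in range(spec.copies_per_family)]

    # one master element per family: real copies are near-identical over
    # their whole length because they descend from the same active element
    masters = {fam: _build_element(templates[fam], rng, spec.gc_fraction)
               for fam in fams}

    inserts = []
    truth = TruthSet()
    for fam, i in plan:
        tpl = templates[fam]
        element, layout = masters[fam]
        status = "full"
        if spec.truncation_probability > 0 and rng.random() < spec.truncation_probability:
            status = "truncated"
            cut = layout["tir_len"] + 25 + len(_STOP_BLOCK) + (
                (layout["orf_end"] - layout["orf_start"]) * 2 // 5) // 3 * 3
            element = element[cut:]
            layout = {"tir_len": 0, "orf_start": None, "orf_end": None,
                      "right_tir_len": len(tpl.tir_seed)}
        elif spec.substitution_rate > 0:
            status = "decayed"
            element = _substitute_dna(element, spec.substitution_rate, rng)
        inserts.append((fam, i, tpl, element, layout, status))

    flank = 2000
    min_len = sum(len(e[3]) + 2 * len(e[2].tsd_class) for e in inserts) \
        + flank * (len(inserts) + 1)
    if spec.genome_length < min_len:
        raise ValueError(
            f"genome_length {spec.genome_length} too short for "
            f"{len(inserts)} copies (need >= {min_len})"
        )
    spare = spec.genome_length - min_len
    gaps = [flank] * (len(inserts) + 1)
    if spare > 0:
        extra = rng.multinomial(spare, [1 / len(gaps)] * len(gaps))
        gaps = [g + int(x) for g, x in zip(gaps, extra)]

    parts: List[str] = []
    pos = 0
    order = rng.permutation(len(inserts))
    prev_junction = None  # (left context, tsd) of the previous copy
    for k, idx in enumerate(order):
        fam, i, tpl, element, layout, status = inserts[idx]
        bg = _background(rng, gaps[k], spec.gc_fraction)
        bg = _disambiguate_tsd(prev_junction, bg)
        parts.append(bg)
        pos += len(bg)
        tsd = tpl.tsd_class
        parts.append(tsd)
        pos += len(tsd)
        start = pos
        parts.append(element)
        pos += len(element)
        end = pos
        parts.append(tsd)
        pos += len(tsd)
        tl = layout["tir_len"]
        tir_left = Interval(seq_id, start, start + tl) if tl else None
        rt = layout.get("right_tir_len", tl)
        tir_right = Interval(seq_id, end - rt, end) if rt else None
        orf = None
        if layout.get("orf_start") is not None:
            orf = Interval(seq_id, start + layout["orf_start"],
                           start + layout["orf_end"])
        truth.copies.append(TruthCopy(
            copy_id=f"{fam}_{i + 1}", family=fam,
            locus=Interval(seq_id, start, end),
            tir_left=tir_left, tir_right=tir_right, tsd=tsd,
            orf=orf, status=status, element_seq=element,
        ))
        prev_junction = (bg + tsd, tsd)
    parts.append(_disambiguate_tsd(
        prev_junction, _background(rng, gaps[-1], spec.gc_fraction)))
    genome = GenomicSequence(id=seq_id, residues="".join(parts))

    contigs = [genome]
    for c in range(spec.n_contaminant_contigs):
        fam = fams[c % len(fams)]
        tpl = templates[fam]
        element, layout = _build_element(tpl, rng, spec.gc_fraction)
        cid = f"contam_{c + 1}"
        left = _background(rng, 600, spec.gc_fraction)
        right = _background(rng, 600, spec.gc_fraction)
        tsd = tpl.tsd_class
        residues = left + tsd + element + tsd + right
        start = len(left) + len(tsd)
        end = start + len(element)
        contigs.append(GenomicSequence(id=cid, residues=residues))
        truth.copies.append(TruthCopy(
            copy_id=f"{fam}_contam{c + 1}", family=fam,
            locus=Interval(cid, start, end),
            tir_left=Interval(cid, start, start + layout["tir_len"]),
            tir_right=Interval(cid, end - layout["tir_len"], end),
            tsd=tsd,
            orf=Interval(cid, start + layout["orf_start"], start + layout["orf_end"]),
            status="full", element_seq=element, contaminant=True,
        ))
    return contigs, truth


# ---------------------------------------------------------------------------
# codon evolution


def _evolve_cds(cds: str, divergence: float, omega: float,
                rng: np.random.Generator) -> str:
    """Evolve a CDS to an expected ``divergence`` accepted substitutions/site.

    Proposal: uniform single-nucleotide codon changes; stops rejected;
    synonymous changes always accepted, nonsynonymous with probability omega.
    """
    if len(cds) % 3:
        raise ValueError("CDS length must be a multiple of 3")
    n_target = rng.binomial(len(cds), min(divergence, 1.0))
    out = list(cds)
    accepted = 0
    max_props = int(n_target / max(omega, 1e-3) * 20) + 2000
    props = 0
    while accepted < n_target and props < max_props:
        props += 1
        pos = int(rng.integers(len(out)))
        old = out[pos]
        new = "ACGT"[("ACGT".index(old) + 1 + int(rng.integers(3))) % 4]
        cstart = pos - pos % 3
        codon_old = "".join(out[cstart : cstart + 3])
        codon_new = codon_old[: pos - cstart] + new + codon_old[pos - cstart + 1 :]
        if codon_new in STOP_CODONS:
            continue
        if translate_codon(codon_new) != translate_codon(codon_old):
            if rng.random() >= omega:
                continue
        out[pos] = new
        accepted += 1
    return "".join(out)


def evolve_codon_pair(n_codons: int, omega: float, divergence: float,
                      seed: int) -> Tuple[str, str]:
    """A gapless aligned codon-sequence pair at the given total divergence.

    The ancestor is random non-stop codons; each lineage accumulates
    ``divergence / 2`` expected substitutions/site under the accept/reject
    codon model. Output strings have length ``3 * n_codons``.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    codons = []
    while len(codons) < n_codons:
        c = "".join(rng.choice(list("ACGT"), size=3))
        if c not in STOP_CODONS:
            codons.append(c)
    anc = "".join(codons)
    a = _evolve_cds(anc, divergence / 2, omega, rng)
    b = _evolve_cds(anc, divergence / 2, omega, rng)
    return a, b


def generate_domesticated_clade(
    spec: SynthSpec,
    template: FamilyTemplate,
    clade_id: str = "clade1",
    kind: str = "domesticated",
) -> TruthClade:
    """Per-species CDS copies of a transposase-derived gene clade.

    ``domesticated``: one single-copy CDS per species, star phylogeny, each
    branch carrying ``divergence / 2`` expected substitutions/site accepted
    under ``spec.omega`` (no flanking TIR/TSD context is generated).
    ``pseudogene-like``: >= 4 copies per species evolving neutrally at an
    inflated rate, so mean pairwise protein identity falls below 70%.
    """
    if spec.n_species < 2:
        raise ValueError("n_species must be >= 2")
    rng = np.random.default_rng([spec.rng_seed, 17])
    anc = back_translate(template.tpase_protein)
    clade = TruthClade(clade_id=clade_id, kind=kind, family=template.family,
                       omega=spec.omega if kind == "domesticated" else 1.0)
    if kind == "domesticated":
        branch_div, omega, n_copies = spec.divergence / 2, spec.omega, 1
    elif kind == "pseudogene-like":
        branch_div, omega, n_copies = max(spec.divergence, 0.25), 1.0, \
            max(4, spec.copies_per_family)
    else:
        raise ValueError(f"unknown clade kind {kind!r}")
    for s in range(spec.n_species):
        species = f"sp{s + 1}"
        clade.species.append(species)
        clade.cds[species] = [
            _evolve_cds(anc, branch_div, omega, rng) for _ in range(n_copies)
        ]
    return clade
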