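"""Family templates and the packaged reference panel.

The pogo superfamily is modelled here as seven families (Passer, Tigger,
pogoR, Lemi, Mover, Fot and Fot-like) whose diagnostic features follow the
published survey: DDE-triad spacings (Passer/Fot/Fot-like DD35D, Mover DD36D,
Tigger within the DD29-36D band, pogoR within DD29-59D/E, Lemi within
DD29-42D), TSD classes (TA for most families, TAA for Fot, TAAA for
Fot-like), TIR length bands, and the five N-terminal DNA-binding-domain
motifs (CENP-B_N, HTH_ABP1_N, HTH_Tnp_Tc5, BrkDBD, HTH_psq).

Because no real transposase catalogue ships with the package, every template
protein, motif consensus and panel catalytic domain is SYNTHETIC: generated
once from a fixed seed so the panel is deterministic and self-consistent.
Real-data users can substitute their own panel through the same interfaces.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

AA20 = "ACDEFGHIKLMNPQRSTVWY"
DNA4 = "ACGT"

_PANEL_SEED = 70214  # fixed: the panel is part of the package, not a dial

DBD_MOTIF_NAMES = ("CENP-B_N", "HTH_ABP1_N", "HTH_Tnp_Tc5", "BrkDBD", "HTH_psq")
FUSION_DOMAIN_NAMES = ("KRAB", "ZNF", "CENP-B_dimeris")

DOMAIN_LEN = 130  # catalytic-domain length shared by all panel members
_R1_COL, _R2_COL = 38, 58  # triad columns r1, r2 within the domain
ALLOWED_THIRD = set("DENSG")


@dataclass(frozen=True)
class FamilyDef:
    name: str
    spacing: int          # residues strictly between r2 and r3
    third: str            # third triad residue
    tir_len: int
    tir_type: int
    tsd_class: str
    dbd_motifs: Tuple[str, ...]


FAMILY_DEFS: Tuple[FamilyDef, ...] = (
    FamilyDef("Passer", 35, "D", 28, 1, "TA", ("BrkDBD", "HTH_Tnp_Tc5")),
    FamilyDef("Tigger", 32, "D", 24, 1, "TA", ("CENP-B_N", "HTH_Tnp_Tc5")),
    FamilyDef("pogoR", 45, "E", 30, 1, "TA", ("CENP-B_N", "HTH_Tnp_Tc5")),
    FamilyDef("Lemi", 38, "D", 26, 1, "TA", ("HTH_ABP1_N", "HTH_Tnp_Tc5")),
    FamilyDef("Mover", 36, "D", 32, 1, "TA", ()),  # DBD not detectable
    FamilyDef("Fot", 35, "D", 48, 2, "TAA", ("HTH_psq", "HTH_Tnp_Tc5")),
    FamilyDef("FotLike", 35, "D", 52, 2, "TAAA", ("HTH_psq",)),
)

FAMILY_NAMES = tuple(fd.name for fd in FAMILY_DEFS)


def _rand_aa(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AA20), size=n))


def _rand_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(DNA4), size=n))


@lru_cache(maxsize=None)
def motif_consensus() -> Dict[str, str]:
    """Synthetic 40-aa consensus blocks for the five DBD motifs and the
    fusion domains seen in chimeric domesticated genes."""
    rng = np.random.default_rng([_PANEL_SEED, 1])
    out = {}
    for name in DBD_MOTIF_NAMES + FUSION_DOMAIN_NAMES:
        out[name] = _rand_aa(rng, 40)
    return out


@lru_cache(maxsize=None)
def _ancestral_domain() -> str:
    """The shared ancestral catalytic-domain background.

    Families are derived from one ancestor so that inter-family identity
    sits near the 30-45% typical of diverged transposase families rather
    than at random-sequence levels."""
    rng = np.random.default_rng([_PANEL_SEED, 0])
    return _rand_aa(rng, DOMAIN_LEN)


_BETWEEN_FAMILY_DIVERGENCE = 0.55


def _family_domain(fd: FamilyDef, rng: np.random.Generator) -> Tuple[str, Tuple[int, int, int]]:
    """A synthetic catalytic domain with the family's triad planted."""
    r3_col = _R2_COL + fd.spacing + 1
    if r3_col >= DOMAIN_LEN - 5:
        raise ValueError(f"domain too short for spacing {fd.spacing}")
    residues = list(_mutate_protein(_ancestral_domain(),
                                    _BETWEEN_FAMILY_DIVERGENCE, rng))
    residues[_R1_COL] = "D"
    residues[_R2_COL] = "D"
    residues[r3_col] = fd.third
    return "".join(residues), (_R1_COL, _R2_COL, r3_col)


def _mutate_protein(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    frozen: Sequence[int] = (),
) -> str:
    """Substitution-only divergence, never touching frozen positions."""
    frozen = set(frozen)
    out = list(seq)
    for i in range(len(out)):
        if i in frozen:
            continue
        if rng.random() < rate:
            choices = [a for a in AA20 if a != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


@dataclass(frozen=True)
class FamilyTemplate:
    """A full-length synthetic transposase template for one family."""

    family: str
    tpase_protein: str
    triad_positions: Tuple[int, int, int]   # protein coords of r1, r2, r3
    dbd_blocks: Tuple[Tuple[str, int, int], ...]  # (motif, start, end)
    domain_span: Tuple[int, int]            # catalytic domain on the protein
    tir_seed: str
    tir_type: int
    tsd_class: str

    def __post_init__(self):
        r1, r2, r3 = self.triad_positions
        p = self.tpase_protein
        if p[r1] != "D" or p[r2] != "D" or p[r3] not in ALLOWED_THIRD:
            raise ValueError(f"{self.family}: triad residues violate D/D/DENSG")
        if len(p) < 300:
            raise ValueError(f"{self.family}: template transposase < 300 aa")
        bands = {1: (1, 40), 2: (41, 60), 3: (61, 200), 4: (201, 10**9)}
        lo, hi = bands[self.tir_type]
        if not (lo <= len(self.tir_seed) <= hi):
            raise ValueError(f"{self.family}: TIR length outside type band")

    @property
    def spacing(self) -> int:
        return self.triad_positions[2] - self.triad_positions[1] - 1

    @property
    def triad_label(self) -> str:
        p = self.tpase_protein
        r1, r2, r3 = self.triad_positions
        return f"{p[r1]}{p[r2]}{self.spacing}{p[r3]}"

    @property
    def domain(self) -> str:
        s, e = self.domain_span
        return self.tpase_protein[s:e]


@lru_cache(maxsize=None)
def build_templates() -> Dict[str, FamilyTemplate]:
    """The packaged synthetic family templates (deterministic)."""
    motifs = motif_consensus()
    templates = {}
    for idx, fd in enumerate(FAMILY_DEFS):
        rng = np.random.default_rng([_PANEL_SEED, 2, idx])
        parts = ["M" + _rand_aa(rng, 5)]
        blocks = []
        for motif in fd.dbd_motifs:
            parts.append(_rand_aa(rng, 6))
            start = sum(len(p) for p in parts)
            parts.append(motifs[motif])
            blocks.append((motif, start, start + len(motifs[motif])))
        parts.append(_rand_aa(rng, 10))
        dstart = sum(len(p) for p in parts)
        domain, (c1, c2, c3) = _family_domain(fd, rng)
        parts.append(domain)
        dend = dstart + DOMAIN_LEN
        tail = max(0, 360 - dend)
        parts.append(_rand_aa(rng, tail + 20))
        protein = "".join(parts)
        templates[fd.name] = FamilyTemplate(
            family=fd.name,
            tpase_protein=protein,
            triad_positions=(dstart + c1, dstart + c2, dstart + c3),
            dbd_blocks=tuple(blocks),
            domain_span=(dstart, dend),
            tir_seed=_rand_dna(rng, fd.tir_len),
            tir_type=fd.tir_type,
            tsd_class=fd.tsd_class,
        )
    return templates


@dataclass(frozen=True)
class PanelMember:
    id: str
    family: str
    domain: str                      # ungapped catalytic domain, DOMAIN_LEN aa
    triad_cols: Tuple[int, int, int]  # triad columns within the domain

    @property
    def triad_label(self) -> str:
        c1, c2, c3 = self.triad_cols
        return f"{self.domain[c1]}{self.domain[c2]}{c3 - c2 - 1}{self.domain[c3]}"


@dataclass(frozen=True)
class ReferencePanel:
    """Family-labelled catalytic domains with annotated triad columns.

    All members share DOMAIN_LEN columns (substitution-only divergence), so
    the panel is its own multiple alignment.
    """

    members: Tuple[PanelMember, ...]

    def families(self) -> List[str]:
        return sorted({m.family for m in self.members})

    def by_family(self, family: str) -> List[PanelMember]:
        return [m for m in self.members if m.family == family]

    def get(self, member_id: str) -> PanelMember:
        for m in self.members:
            if m.id == member_id:
                return m
        raise KeyError(member_id)

    def drop(self, member_id: str) -> "ReferencePanel":
        kept = tuple(m for m in self.members if m.id != member_id)
        return ReferencePanel(members=kept)


@lru_cache(maxsize=None)
def load_reference_panel(n_per_family: int = 3,
                         within_divergence: float = 0.10) -> ReferencePanel:
    """The packaged synthetic reference panel.

    Each family contributes its template's catalytic domain plus
    ``n_per_family - 1`` variants diverged by substitution at
    ``within_divergence`` per site (triad columns frozen).
    """
    templates = build_templates()
    members = []
    for idx, fd in enumerate(FAMILY_DEFS):
        tpl = templates[fd.name]
        dstart, _ = tpl.domain_span
        cols = tuple(p - dstart for p in tpl.triad_positions)
        members.append(PanelMember(f"{fd.name}_ref1", fd.name, tpl.domain, cols))
        rng = np.random.default_rng([_PANEL_SEED, 3, idx])
        for v in range(2, n_per_family + 1):
            variant = _mutate_protein(tpl.domain, within_divergence, rng,
                                      frozen=cols)
            members.append(PanelMember(f"{fd.name}_ref{v}", fd.name, variant, cols))
    return ReferencePanel(members=tuple(members))
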