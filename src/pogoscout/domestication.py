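"""Domesticated-gene calling: transposon/gene discrimination, clade filters,
and a from-scratch Nei-Gojobori (NG86) Ka/Ks with a codon-based Z-test.

A transposase-derived locus with no detectable TIR or TSD in its flanks is a
putative domesticated gene; candidate clades then face the survey's stringent
filters (mean protein identity >= 70%, at least five species, at most three
copies per genome) and must show purifying selection: Ka/Ks < 1 with a
one-tailed Z-test at P < 0.05, the variance of (Ks - Ka) estimated by
bootstrap over codons (100 replicates).

NG86 here follows the conventional resolution of the stop-codon corner
cases: single-nucleotide mutations to stop codons count as nonsynonymous in
site counting, and evolutionary pathways passing through a stop codon are
excluded from the difference-count average (when every pathway crosses a
stop, all are used with stop steps counted nonsynonymous).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import norm
from Bio.Seq import Seq

from .alignment import aligned_identity, protein_aligner
from .boundary import call_tsd, find_tir
from .config import PipelineConfig
from .families import FUSION_DOMAIN_NAMES, ReferencePanel, load_reference_panel
from .model import GenomicSequence, Interval
from .structure import assign_dbd_architecture
from .synth import STOP_CODONS

logger = logging.getLogger(__name__)

_NUC = "ACGT"


def _translate(codon: str) -> str:
    return str(Seq(codon).translate())


@lru_cache(maxsize=None)
def ng86_sites(codon: str) -> Tuple[float, float]:
    """Nonsynonymous and synonymous site counts (n, s) of one codon.

    Each position contributes the fraction of its three single-nucleotide
    changes that are synonymous; changes creating stop codons count as
    nonsynonymous. Always n + s = 3.
    """
    if len(codon) != 3 or any(b not in _NUC for b in codon):
        raise ValueError(f"invalid codon {codon!r}")
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no NG86 sites")
    aa = _translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _NUC:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in STOP_CODONS and _translate(alt) == aa:
                syn += 1
        s += syn / 3.0
    return 3.0 - s, s


@lru_cache(maxsize=None)
def ng86_differences(codon_a: str, codon_b: str) -> Tuple[float, float]:
    """Nonsynonymous and synonymous difference counts (nd, sd) for a codon
    pair, averaged over all mutational pathways with non-stop intermediates."""
    diffs = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diffs:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diffs):
        steps = []
        cur = codon_a
        crosses_stop = False
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS and nxt != codon_b:
                crosses_stop = True
            syn = (nxt not in STOP_CODONS and cur not in STOP_CODONS
                   and _translate(nxt) == _translate(cur))
            steps.append(syn)
            cur = nxt
        paths.append((crosses_stop, steps))
    valid = [steps for crossed, steps in paths if not crossed]
    if not valid:  # all pathways cross stops: use all, stop steps nonsynonymous
        valid = [steps for _, steps in paths]
    sd = sum(sum(steps) for steps in valid) / len(valid)
    nd = len(diffs) - sd
    return nd, sd


@dataclass
class KaKsResult:
    """NG86 estimates for one aligned coding-sequence pair."""

    n_sites: float
    s_sites: float
    nd: float
    sd: float
    n_codons: int               # comparable (gap/ambiguity-free) codons
    ka: float = float("nan")    # nonsynonymous substitutions per nonsyn site
    ks: float = float("nan")    # synonymous substitutions per syn site
    var_ka: float = float("nan")
    var_ks: float = float("nan")
    var_diff: float = float("nan")  # bootstrap var of (Ks - Ka)
    z: float = float("nan")
    p: float = float("nan")
    verdict: str = "undefined"  # purifying | not_significant | undefined

    @property
    def ratio(self) -> Optional[float]:
        """Ka/Ks, or None when undefined (Ks = 0 or either rate undefined)."""
        if np.isnan(self.ka) or np.isnan(self.ks) or self.ks == 0.0:
            return None
        return self.ka / self.ks


def _jc(p: float) -> float:
    """Jukes-Cantor correction; NaN when p >= 3/4 (rate undefined)."""
    if p >= 0.75:
        return float("nan")
    if p <= 0.0:
        return 0.0
    return -0.75 * np.log(1.0 - 4.0 * p / 3.0)


def _codon_arrays(a: str, b: str):
    """Per-codon (n, s, nd, sd) arrays over comparable codon pairs."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    if len(a) % 3:
        raise ValueError("alignment length must be a multiple of 3")
    rows = []
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if any(x not in _NUC for x in ca + cb):
            continue  # gap or ambiguous codon: excluded pairwise
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        na, sa = ng86_sites(ca)
        nb, sb = ng86_sites(cb)
        nd, sd = ng86_differences(ca, cb)
        rows.append(((na + nb) / 2, (sa + sb) / 2, nd, sd))
    return np.array(rows).reshape(-1, 4)


def _rates(arr: np.ndarray) -> Tuple[float, float]:
    n, s = arr[:, 0].sum(), arr[:, 1].sum()
    nd, sd = arr[:, 2].sum(), arr[:, 3].sum()
    pn = nd / n if n > 0 else float("nan")
    ps = sd / s if s > 0 else float("nan")
    return _jc(pn), _jc(ps)


def ng86_pair(a: str, b: str) -> KaKsResult:
    """NG86 Ka and Ks for an aligned, frame-preserved CDS pair.

    Site counts are averaged over the two sequences; multi-change codons
    average difference counts over all stop-free mutational orderings;
    proportions receive the Jukes-Cantor correction.
    """
    arr = _codon_arrays(a, b)
    res = KaKsResult(
        n_sites=float(arr[:, 0].sum()), s_sites=float(arr[:, 1].sum()),
        nd=float(arr[:, 2].sum()), sd=float(arr[:, 3].sum()),
        n_codons=arr.shape[0],
    )
    if arr.shape[0] == 0:
        return res
    res.ka, res.ks = _rates(arr)
    return res


def kaks_z_test(a: str, b: str, n_boot: int = 100, alpha: float = 0.05,
                seed: int = 0) -> KaKsResult:
    """Complete an NG86 result with the bootstrap Z-test for purifying
    selection (one-tailed alternative Ks > Ka).

    Codons are resampled with replacement ``n_boot`` times; the variance of
    (Ks - Ka) over replicates gives Z = (Ks - Ka)/SE and a one-tailed P.
    Verdict 'purifying' requires Ka/Ks < 1 (Ka < Ks) and P < alpha; fewer
    than 10 comparable codons leaves the verdict undefined.
    """
    res = ng86_pair(a, b)
    arr = _codon_arrays(a, b)
    if res.n_codons < 10:
        logger.warning("only %d comparable codons: verdict undefined",
                       res.n_codons)
        return res
    if np.isnan(res.ka) or np.isnan(res.ks):
        return res
    rng = np.random.default_rng(seed)
    kas, kss = [], []
    for _ in range(n_boot):
        idx = rng.integers(arr.shape[0], size=arr.shape[0])
        ka_i, ks_i = _rates(arr[idx])
        kas.append(ka_i)
        kss.append(ks_i)
    kas, kss = np.array(kas), np.array(kss)
    ok = ~(np.isnan(kas) | np.isnan(kss))
    if ok.sum() < 2:
        return res
    res.var_ka = float(np.var(kas[ok], ddof=1))
    res.var_ks = float(np.var(kss[ok], ddof=1))
    diff = kss[ok] - kas[ok]
    res.var_diff = float(np.var(diff, ddof=1))
    se = np.sqrt(res.var_diff)
    if se == 0.0:
        res.z = 0.0
        res.p = 0.5
        res.verdict = "not_significant"
        return res
    res.z = float((res.ks - res.ka) / se)
    res.p = float(norm.sf(res.z))
    res.verdict = "purifying" if (res.p < alpha and res.ka < res.ks) \
        else "not_significant"
    return res


# ---------------------------------------------------------------------------
# transposon vs domesticated-gene discrimination


def discriminate_locus(
    genome: GenomicSequence,
    locus: Interval,
    config: Optional[PipelineConfig] = None,
    tir_probes: Sequence[str] = (),
    min_tir_len: int = 16,
) -> str:
    """Classify a homology locus as transposon-like or putatively domesticated.

    The locus extended by its flanks is scanned for a TIR pair (with a TSD
    at the implied boundaries) or, given known family TIR probes, for a
    single TIR on either side; any such hallmark makes the locus
    transposon_like, none makes it putative_domesticated. A locus with both
    flanks truncated by contig edges is indeterminate.

    ``min_tir_len`` is stricter than the annotation default because an
    unanchored scan over +/- 2 kb windows would otherwise hit chance inverted
    repeats.
    """
    from .alignment import best_infix_identity
    from .boundary import polish_boundaries
    from .model import revcomp

    config = config or PipelineConfig()
    start = max(0, locus.start - config.flank_bp)
    end = min(len(genome), locus.end + config.flank_bp)
    if locus.start - start < 50 and end - locus.end < 50:
        logger.warning("locus %s:%d-%d has no usable flanks: indeterminate",
                       locus.seq_id, locus.start, locus.end)
        return "indeterminate"
    window = genome.residues[start:end]
    tirs = find_tir(window, max_tir_len=config.flank_bp + 500,
                    min_tir_len=min_tir_len,
                    min_tir_identity=max(config.min_tir_identity, 0.85),
                    anchor_slack=len(window))
    if tirs is not None and tirs.right is not None:
        # polish the implied element boundaries (the raw inverted-repeat
        # alignment can overshoot into a palindromic TSD), then demand a TSD
        coarse = Interval(genome.id, start + int(tirs.left.start),
                          start + int(tirs.right.end))
        pol = polish_boundaries(genome, coarse, config)
        left_flank = genome.residues[max(0, pol.start - config.tsd_max_k) : pol.start]
        right_flank = genome.residues[pol.end : pol.end + config.tsd_max_k]
        if call_tsd(left_flank, right_flank, config.tsd_max_k).tsd_class != "NONE":
            return "transposon_like"
    left_region = genome.residues[start : locus.start + 50]
    right_region = genome.residues[max(start, locus.end - 50) : end]
    for probe in tir_probes:
        for p, region in ((probe, left_region), (revcomp(probe), right_region),
                          (revcomp(probe), left_region), (probe, right_region)):
            if best_infix_identity(p, region) >= config.min_tir_identity:
                return "transposon_like"
    return "putative_domesticated"


# ---------------------------------------------------------------------------
# clade-level calling


@dataclass
class DomesticationCall:
    clade_id: str
    n_species: int
    mean_protein_identity: float
    max_copies_per_genome: int
    mean_kaks: Optional[float]
    verdict: str                      # stationary_domesticated | pseudogene_like | rejected
    kaks_pairs: List[KaKsResult] = field(default_factory=list)
    reason: str = ""


def _protein(cds: str) -> str:
    return str(Seq(cds[: len(cds) // 3 * 3]).translate()).rstrip("*")


def mean_pairwise_protein_identity(proteins: Sequence[str]) -> float:
    """Mean pairwise global-alignment identity over all protein pairs."""
    aligner = protein_aligner("global")
    idents = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            aln = aligner.align(proteins[i], proteins[j])[0]
            ident, _ = aligned_identity(aln, proteins[i], proteins[j])
            idents.append(ident)
    return float(np.mean(idents)) if idents else 1.0


def call_domestication(
    clade_id: str,
    members: Dict[str, List[str]],      # species -> CDS copies in that genome
    panel: Optional[ReferencePanel] = None,
    alpha: float = 0.05,
    n_boot: int = 100,
    seed: int = 0,
    min_identity: float = 0.70,
    min_species: int = 5,
    max_copies: int = 3,
) -> DomesticationCall:
    """Apply the stringent clade filters and the selection test.

    stationary_domesticated requires mean protein identity >= 70%, at least
    five species, at most three copies per genome, and a purifying Ka/Ks
    verdict (majority of pairwise one-representative-per-species Z-tests
    significant with mean ratio < 1). Multi-copy or low-identity clades that
    still show homology to the transposase panel are pseudogene_like;
    everything else is rejected with a reason.
    """
    panel = panel or load_reference_panel()
    species = sorted(s for s, seqs in members.items() if seqs)
    n_species = len(species)
    copies = max((len(members[s]) for s in species), default=0)
    reps = [members[s][0] for s in species]
    proteins = [_protein(c) for c in reps]
    identity = mean_pairwise_protein_identity(proteins)
    pairs = []
    for i in range(len(reps)):
        for j in range(i + 1, len(reps)):
            la, lb = len(reps[i]) // 3 * 3, len(reps[j]) // 3 * 3
            L = min(la, lb)
            pairs.append(kaks_z_test(reps[i][:L], reps[j][:L],
                                     n_boot=n_boot, alpha=alpha,
                                     seed=seed + i * 1000 + j))
    ratios = [p.ratio for p in pairs if p.ratio is not None]
    mean_ratio = float(np.mean(ratios)) if ratios else None
    n_purifying = sum(1 for p in pairs if p.verdict == "purifying")
    purifying = bool(pairs) and n_purifying > len(pairs) / 2 and (
        mean_ratio is None or mean_ratio < 1.0)

    from .phylo import extract_dde_domain  # local import: avoid cycle
    panel_homology = any(
        extract_dde_domain(p, panel) is not None for p in proteins[:3])

    if (identity >= min_identity and n_species >= min_species
            and copies <= max_copies and purifying):
        verdict, reason = "stationary_domesticated", ""
    elif (copies > max_copies or identity < min_identity) and panel_homology:
        verdict = "pseudogene_like"
        reason = (f"copies={copies}" if copies > max_copies
                  else f"identity={identity:.2f}")
    else:
        verdict = "rejected"
        bits = []
        if n_species < min_species:
            bits.append(f"only {n_species} species")
        if not purifying:
            bits.append("no purifying-selection signal")
        if not panel_homology:
            bits.append("no panel homology")
        reason = "; ".join(bits) or "filters failed"
    return DomesticationCall(
        clade_id=clade_id, n_species=n_species,
        mean_protein_identity=identity, max_copies_per_genome=copies,
        mean_kaks=mean_ratio, verdict=verdict, kaks_pairs=pairs,
        reason=reason,
    )


# ---------------------------------------------------------------------------
# chimeric fusion domains


def detect_fusion_domains(
    protein: str,
    domtbl_rows: Optional[Sequence[tuple]] = None,
    query_id: Optional[str] = None,
    threshold: float = 0.70,
) -> List[str]:
    """Extra functional domains beyond the transposase DBD/DDE repertoire.

    Scans the packaged fusion-domain consensus set (KRAB, ZNF and the
    CENP-B dimerisation domain) or an ingested per-domain hit table; any
    such domain marks the protein as chimeric. Returned in N->C order.
    """
    if domtbl_rows is not None:
        names = set()
        for (target, qname, _ev, _f, _t, _s) in domtbl_rows:
            if query_id is not None and qname != query_id:
                continue
            names.add(target)
        fusion_names = tuple(sorted(n for n in names
                                    if n in FUSION_DOMAIN_NAMES))
        return assign_dbd_architecture(protein, motif_names=fusion_names,
                                       domtbl_rows=domtbl_rows,
                                       query_id=query_id)
    return assign_dbd_architecture(protein, motif_names=FUSION_DOMAIN_NAMES,
                                   threshold=threshold)


def is_chimeric(protein: str, **kwargs) -> bool:
    return len(detect_fusion_domains(protein, **kwargs)) > 0
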