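"""Candidate-locus discovery by translated homology and copy-number rules.

A built-in six-frame seeded scan (k-mer seeds, ungapped BLOSUM62 extension
with X-drop) stands in for TBlastN on desk-scale genomes; precomputed
12-column tabular hits can be ingested instead via :mod:`pogoscout.io`.
Downstream rules follow the survey's mining procedure: top 10 non-overlapping
hits per query extracted with 2-kb flanks, copies counted from alignments
> 1000 bp at > 80% identity, and a flank-mapping contamination check for
elements with fewer than 3 copies.
"""
from __future__ import annotations

import logging
from collections import defaultdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from .alignment import best_infix_identity, find_copies
from .config import PipelineConfig
from .model import (CandidateLocus, CopyNumberReport, GenomicSequence,
                    HitRecord, Interval, revcomp)

logger = logging.getLogger(__name__)

_BLOSUM = substitution_matrices.load("BLOSUM62")
_SEED_K = 4
_XDROP = 15.0


def _blosum(a: str, b: str) -> float:
    try:
        return _BLOSUM[a, b]
    except (KeyError, IndexError):
        return -4.0


def _six_frames(genome: GenomicSequence):
    """Yield (frame_id, strand, offset, protein) for all six frames.

    ``offset`` is the nt offset of aa position 0 on the *forward* strand for
    (+) frames and on the reverse-complemented sequence for (-) frames.
    """
    fwd = genome.residues
    rev = revcomp(fwd)
    for f in range(3):
        for strand, seq in (("+", fwd), ("-", rev)):
            trimmed = seq[f : f + (len(seq) - f) // 3 * 3]
            if len(trimmed) < 3:
                continue
            yield f, strand, str(Seq(trimmed).translate())


def _frame_to_genomic(strand: str, frame: int, aa_start: int, aa_end: int,
                      genome_len: int, seq_id: str) -> Interval:
    nt_start = frame + 3 * aa_start
    nt_end = frame + 3 * aa_end
    if strand == "+":
        return Interval(seq_id, nt_start, nt_end, "+")
    return Interval(seq_id, genome_len - nt_end, genome_len - nt_start, "-")


def translated_scan(
    queries: Sequence[Tuple[str, str]],
    genome: GenomicSequence,
    min_score: float = 60.0,
) -> List[HitRecord]:
    """Scan a genome with protein queries through six-frame translation.

    Exact 4-aa k-mer seeds are extended without gaps under BLOSUM62 scoring
    with an X-drop of 15; hits scoring at least ``min_score`` are reported as
    HitRecords ranked by score. Deterministic for fixed inputs. The e-value
    field is set to 0 (the built-in scan reports scores, not statistics).
    """
    hits: List[HitRecord] = []
    for qid, qseq in queries:
        if not qseq:
            raise ValueError(f"empty query {qid!r}")
        index: Dict[str, List[int]] = defaultdict(list)
        for i in range(len(qseq) - _SEED_K + 1):
            index[qseq[i : i + _SEED_K]].append(i)
        for frame, strand, prot in _six_frames(genome):
            # seeds grouped by diagonal; one extension per covered stretch
            covered: Dict[int, int] = {}  # diagonal -> rightmost qpos covered
            for t in range(len(prot) - _SEED_K + 1):
                kmer = prot[t : t + _SEED_K]
                for q in index.get(kmer, ()):
                    diag = t - q
                    if covered.get(diag, -1) >= q:
                        continue
                    score, qs, qe = _extend(qseq, prot, q, t)
                    covered[diag] = qe
                    if score < min_score:
                        continue
                    ts, te = qs + diag, qe + diag
                    matches = sum(
                        1 for k in range(qe - qs)
                        if qseq[qs + k] == prot[ts + k] and qseq[qs + k] != "X"
                    )
                    target = _frame_to_genomic(strand, frame, ts, te,
                                               len(genome), genome.id)
                    hits.append(HitRecord(
                        query_id=qid, target=target,
                        percent_identity=matches / (qe - qs),
                        alignment_length=qe - qs,
                        evalue=0.0, bit_score=score,
                    ))
    hits.sort(key=lambda h: (-h.bit_score, h.target.seq_id, h.target.start))
    return _dedupe(hits)


def _extend(qseq: str, prot: str, q: int, t: int) -> Tuple[float, int, int]:
    """Ungapped X-drop extension around a seed; returns (score, qstart, qend)."""
    score = sum(_blosum(qseq[q + k], prot[t + k]) for k in range(_SEED_K))
    best = score
    qs, qe = q, q + _SEED_K
    # extend right
    cur, i = best, 0
    bi = 0
    while q + _SEED_K + i < len(qseq) and t + _SEED_K + i < len(prot):
        cur += _blosum(qseq[q + _SEED_K + i], prot[t + _SEED_K + i])
        i += 1
        if cur > best:
            best, bi = cur, i
        if best - cur > _XDROP:
            break
    qe = q + _SEED_K + bi
    # extend left
    cur, i = best, 0
    bi = 0
    while q - 1 - i >= 0 and t - 1 - i >= 0:
        cur += _blosum(qseq[q - 1 - i], prot[t - 1 - i])
        i += 1
        if cur > best:
            best, bi = cur, i
        if best - cur > _XDROP:
            break
    qs = q - bi
    return best, qs, qe


def _dedupe(hits: List[HitRecord]) -> List[HitRecord]:
    """Drop hits whose genomic span is contained in a better same-query hit."""
    kept: List[HitRecord] = []
    for h in hits:
        redundant = any(
            k.query_id == h.query_id
            and k.target.seq_id == h.target.seq_id
            and k.target.start <= h.target.start
            and h.target.end <= k.target.end
            for k in kept
        )
        if not redundant:
            kept.append(h)
    return kept


def select_top_hits(
    hits: Sequence[HitRecord],
    genome: GenomicSequence,
    config: Optional[PipelineConfig] = None,
) -> List[CandidateLocus]:
    """Per query: greedy best-score non-overlapping hits, capped at top 10.

    "Non-overlapping" means sharing no base with an already-retained hit.
    Each retained locus gets flanks of up to ``flank_bp``, clipped at contig
    ends.
    """
    config = config or PipelineConfig()
    by_query: Dict[str, List[HitRecord]] = defaultdict(list)
    for h in hits:
        by_query[h.query_id].append(h)
    loci: List[CandidateLocus] = []
    for qid in sorted(by_query):
        ranked = sorted(by_query[qid],
                        key=lambda h: (-h.bit_score, h.target.start))
        retained: List[HitRecord] = []
        for h in ranked:
            if len(retained) >= config.top_hits_per_query:
                break
            if any(h.target.overlaps(r.target) for r in retained):
                continue
            retained.append(h)
        for h in retained:
            iv = h.target
            left = genome.residues[max(0, iv.start - config.flank_bp) : iv.start]
            right = genome.residues[iv.end : iv.end + config.flank_bp]
            loci.append(CandidateLocus(locus=iv, supporting_hits=[h],
                                       flank_left=left, flank_right=right))
    loci.sort(key=lambda l: (l.locus.seq_id, l.locus.start))
    return loci


def count_copies(
    representative: str,
    genome: GenomicSequence,
    config: Optional[PipelineConfig] = None,
    representative_id: str = "representative",
) -> CopyNumberReport:
    """Count non-overlapping genomic copies of a representative element.

    Copies are edit-distance alignments of the element (either orientation)
    longer than ``copy_min_len_bp`` at identity above ``copy_min_identity``,
    mirroring the survey's "BLAST hits > 1000 bp and > 80% identity" rule.
    """
    config = config or PipelineConfig()
    if len(representative) < config.copy_min_len_bp:
        raise ValueError(
            f"representative shorter than copy_min_len_bp "
            f"({len(representative)} < {config.copy_min_len_bp})"
        )
    text = genome.residues
    fwd = find_copies(representative, text,
                      config.copy_min_len_bp, config.copy_min_identity)
    masked = list(text)
    for s, e, _ in fwd:
        for i in range(s, e):
            masked[i] = "\x00"
    rev = find_copies(revcomp(representative), "".join(masked),
                      config.copy_min_len_bp, config.copy_min_identity)
    n = len(fwd) + len(rev)
    return CopyNumberReport(representative_id=representative_id,
                            n_copies=max(n, 1))


def contamination_check(
    locus: CandidateLocus,
    report: CopyNumberReport,
    contigs: Sequence[GenomicSequence],
    config: Optional[PipelineConfig] = None,
) -> bool:
    """Return True when a low-copy locus should be excluded as contamination.

    Applied only when ``n_copies < low_copy_threshold``: both flanks (up to
    200 bp each) are mapped back to the assembly with the locus and its own
    flank neighbourhood masked out; the locus is excluded when neither flank
    finds a home at >= 90% identity. Elements at or above the copy threshold
    always pass. Flanks shorter than 50 bp skip the check with a warning.
    """
    config = config or PipelineConfig()
    if report.n_copies >= config.low_copy_threshold:
        return False
    left = locus.flank_left[-config.contam_flank_bp :]
    right = locus.flank_right[: config.contam_flank_bp]
    if len(left) < 50 or len(right) < 50:
        logger.warning(
            "contamination check skipped for %s:%d-%d: flanks too short",
            locus.locus.seq_id, locus.locus.start, locus.locus.end,
        )
        return False
    for flank in (left, right):
        for contig in contigs:
            text = contig.residues
            if contig.id == locus.locus.seq_id:
                mask_start = max(0, locus.locus.start - len(locus.flank_left))
                mask_end = min(len(text), locus.locus.end + len(locus.flank_right))
                text = (text[:mask_start] + "\x00" * (mask_end - mask_start)
                        + text[mask_end:])
            for probe in (flank, revcomp(flank)):
                if best_infix_identity(probe, text) >= config.contam_flank_identity:
                    return False
    return True
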