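"""Internal pairwise/multiple alignment helpers.

Protein alignment is Bio.Align.PairwiseAligner with BLOSUM62 (affine gaps);
DNA copy search is edlib edit-distance alignment; the multiple alignment used
for boundary refinement is a center-star construction over edlib global
pairwise paths. N bases never count as matches in any identity computed here.
"""
from __future__ import annotations

import re
from functools import lru_cache
from typing import List, Optional, Sequence, Tuple

import edlib
from Bio.Align import PairwiseAligner, substitution_matrices

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@lru_cache(maxsize=None)
def protein_aligner(mode: str = "global") -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = mode
    return al


@lru_cache(maxsize=None)
def dna_aligner(mode: str = "local") -> PairwiseAligner:
    al = PairwiseAligner()
    al.match_score = 2.0
    al.mismatch_score = -3.0
    al.open_gap_score = -5.0
    al.extend_gap_score = -2.0
    al.mode = mode
    return al


def aligned_identity(alignment, seq_a: str, seq_b: str) -> Tuple[float, int]:
    """(identity, aligned columns incl. internal gaps) of a Bio alignment."""
    blocks_a, blocks_b = alignment.aligned
    matches = 0
    aligned_cols = 0
    prev_a = prev_b = None
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            aligned_cols += max(sa - prev_a, sb - prev_b)  # internal gap columns
        for i in range(ea - sa):
            ca, cb = seq_a[sa + i], seq_b[sb + i]
            if ca == cb and ca != "N":
                matches += 1
        aligned_cols += ea - sa
        prev_a, prev_b = ea, eb
    return (matches / aligned_cols if aligned_cols else 0.0), aligned_cols


def alignment_columns(alignment) -> List[Tuple[Optional[int], Optional[int]]]:
    """Expand a Bio alignment into per-column (a_pos, b_pos) with None = gap."""
    blocks_a, blocks_b = alignment.aligned
    cols: List[Tuple[Optional[int], Optional[int]]] = []
    prev_a = prev_b = None
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        if prev_a is not None:
            for p in range(prev_a, sa):
                cols.append((p, None))
            for p in range(prev_b, sb):
                cols.append((None, p))
        for i in range(ea - sa):
            cols.append((sa + i, sb + i))
        prev_a, prev_b = ea, eb
    return cols


def position_map(alignment) -> dict:
    """Map positions of the second sequence onto the first for a Bio alignment.

    Returns {b_pos: a_pos} over aligned (non-gap) columns.
    """
    blocks_a, blocks_b = alignment.aligned
    mapping = {}
    for (sa, ea), (sb, eb) in zip(blocks_a, blocks_b):
        for i in range(ea - sa):
            mapping[sb + i] = sa + i
    return mapping


# ---------------------------------------------------------------------------
# edlib-backed DNA search


def parse_cigar(cigar: str) -> List[Tuple[int, str]]:
    return [(int(n), op) for n, op in _CIGAR_RE.findall(cigar)]


def find_copies(
    pattern: str,
    text: str,
    min_len: int,
    min_identity: float,
    max_hits: int = 500,
) -> List[Tuple[int, int, float]]:
    """Non-overlapping approximate occurrences of ``pattern`` in ``text``.

    Iterative best-hit search with masking: each round takes the best infix
    (edit-distance) alignment, records it if it passes the length and identity
    thresholds, masks it out and repeats. Identity is 1 - edits/aligned_len.
    """
    text = list(text)
    hits = []
    max_edits = int(len(pattern) * (1.0 - min_identity) * 1.5) + 1
    for _ in range(max_hits):
        res = edlib.align(pattern, "".join(text), mode="HW",
                          task="locations", k=max_edits)
        if res["editDistance"] < 0 or not res["locations"]:
            break
        start, end_inc = res["locations"][0]
        end = end_inc + 1
        aligned_len = end - start
        identity = 1.0 - res["editDistance"] / max(aligned_len, len(pattern))
        if aligned_len > min_len and identity > min_identity:
            hits.append((start, end, identity))
        # mask regardless, so a failing best hit cannot stall the loop
        for i in range(start, end):
            text[i] = "\x00"
        if identity <= min_identity:
            break
    hits.sort()
    return hits


def best_infix_identity(pattern: str, text: str) -> float:
    """Identity of the best infix alignment of pattern in text (0 if none)."""
    if not pattern or not text:
        return 0.0
    res = edlib.align(pattern, text, mode="HW", task="locations")
    if res["editDistance"] < 0:
        return 0.0
    return 1.0 - res["editDistance"] / len(pattern)


# ---------------------------------------------------------------------------
# center-star multiple alignment


def _kmer_set(seq: str, k: int = 8) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def center_star_msa(seqs: Sequence[str]) -> List[str]:
    """Center-star multiple alignment of DNA sequences.

    The center is the sequence with the greatest summed k-mer similarity to
    the others; every other sequence is globally aligned to the center with
    edlib and the pairwise paths are merged on the center's coordinates.
    """
    n = len(seqs)
    if n < 2:
        return list(seqs)
    kmers = [_kmer_set(s) for s in seqs]
    sims = []
    for i in range(n):
        total = 0.0
        for j in range(n):
            if i == j:
                continue
            inter = len(kmers[i] & kmers[j])
            union = len(kmers[i] | kmers[j]) or 1
            total += inter / union
        sims.append(total)
    center = max(range(n), key=lambda i: (sims[i], -i))
    cseq = seqs[center]
    clen = len(cseq)

    # pairwise paths: per sequence, insertions before each center position
    pair_ops = []
    ins_before = [[0] * (clen + 1) for _ in range(n)]
    for j in range(n):
        if j == center:
            pair_ops.append(None)
            continue
        res = edlib.align(seqs[j], cseq, mode="NW", task="path")
        ops = parse_cigar(res["cigar"])
        pair_ops.append(ops)
        cpos = 0
        for length, op in ops:
            if op == "I":  # consumes query only: insertion relative to center
                ins_before[j][cpos] += length
            elif op in ("=", "X", "M"):
                cpos += length
            elif op == "D":  # gap in query, consumes center
                cpos += length
    master_ins = [max(ins_before[j][i] for j in range(n)) for i in range(clen + 1)]

    # build rows
    rows = []
    for j in range(n):
        if j == center:
            parts = []
            for i in range(clen):
                parts.append("-" * master_ins[i])
                parts.append(cseq[i])
            parts.append("-" * master_ins[clen])
            rows.append("".join(parts))
            continue
        sj = seqs[j]
        parts = []
        cpos = 0
        qpos = 0
        pending_ins = ""
        for length, op in pair_ops[j]:
            if op == "I":
                pending_ins += sj[qpos : qpos + length]
                qpos += length
                continue
            for _ in range(length):
                parts.append("-" * (master_ins[cpos] - len(pending_ins)))
                parts.append(pending_ins)
                pending_ins = ""
                if op in ("=", "X", "M"):
                    parts.append(sj[qpos])
                    qpos += 1
                else:  # D: gap in this sequence
                    parts.append("-")
                cpos += 1
        parts.append("-" * (master_ins[clen] - len(pending_ins)))
        parts.append(pending_ins)
        rows.append("".join(parts))
    width = len(rows[center])
    assert all(len(r) == width for r in rows)
    return rows
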