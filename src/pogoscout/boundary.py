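"""Element boundary refinement, TIR and TSD detection, validation rules.

The validation rule is the survey's: an element with two detectable TIRs and
a TSD is a FULL transposon; one TIR plus a TSD plus a transposase of at
least 300 aa is kept as HALF; anything less is DISCARDED (kept in output
with its reason, never silently dropped). TSD classes TA, TAA and TAAA are
distinguished by a longest-exact-match rule so TAAA is never reported as its
substring TA.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .alignment import (aligned_identity, alignment_columns, center_star_msa,
                        dna_aligner)
from .config import PipelineConfig
from .model import CandidateLocus, GenomicSequence, Interval, revcomp

logger = logging.getLogger(__name__)

TSD_CLASSES = ("TA", "TAA", "TAAA")


@dataclass
class TIRPair:
    """A terminal inverted repeat pair (element-local or genomic coords)."""

    left: Interval
    right: Optional[Interval]
    length: int
    identity: float
    tir_type: Optional[int] = None

    def __post_init__(self):
        if self.right is not None and self.left.start >= self.right.start:
            raise ValueError("left TIR must precede right TIR")

    @property
    def n_tirs(self) -> int:
        return 1 if self.right is None else 2


@dataclass(frozen=True)
class TSDCall:
    repeat: str
    tsd_class: str  # TA | TAA | TAAA | OTHER | NONE

    def __post_init__(self):
        if (self.tsd_class == "NONE") != (self.repeat == ""):
            raise ValueError("repeat must be empty iff class is NONE")


@dataclass
class AnnotatedElement:
    """The pipeline's central record: a locus with its structural evidence."""

    locus: Interval
    tirs: Optional[TIRPair]
    tsd: Optional[TSDCall]
    tpase: Optional[object]  # structure.TransposaseAnnotation
    status: str              # FULL | HALF | DISCARDED
    reason: str = ""
    id: str = ""
    family: str = ""


# ---------------------------------------------------------------------------
# TSD


def call_tsd(left_flank: str, right_flank: str, max_k: int = 10) -> TSDCall:
    """Call the target site duplication from the two flanks.

    The repeat is the longest k in [2, max_k] for which the last k bases of
    the left flank exactly equal the first k bases of the right flank
    (longest match wins, so a TAAA site is never down-called to TA).
    """
    best = ""
    kmax = min(max_k, len(left_flank), len(right_flank))
    for k in range(2, kmax + 1):
        if left_flank[-k:] == right_flank[:k]:
            best = left_flank[-k:]
    if not best:
        return TSDCall(repeat="", tsd_class="NONE")
    cls = best if best in TSD_CLASSES else "OTHER"
    return TSDCall(repeat=best, tsd_class=cls)


# ---------------------------------------------------------------------------
# TIR


def find_tir(
    element_seq: str,
    max_tir_len: int = 1000,
    min_tir_len: int = 10,
    min_tir_identity: float = 0.80,
    anchor_slack: int = 5,
) -> Optional[TIRPair]:
    """Detect a terminal inverted repeat pair on an element sequence.

    The first ``max_tir_len`` bases are locally aligned against the reverse
    complement of the last ``max_tir_len`` bases; the best alignment is
    reported when it is anchored within ``anchor_slack`` bp of both termini,
    spans at least ``min_tir_len`` aligned bases and reaches
    ``min_tir_identity``. Coordinates are element-local on seq_id "element".
    """
    L = len(element_seq)
    if L < 2 * min_tir_len:
        return None
    w = min(max_tir_len, L // 2)
    head = element_seq[:w]
    tail_rc = revcomp(element_seq[-w:])
    aligner = dna_aligner("local")
    alns = aligner.align(head, tail_rc)
    if len(alns) == 0 or alns.score <= 0:
        return None
    aln = alns[0]
    cols = alignment_columns(aln)
    if not cols:
        return None
    a_start = next(a for a, _ in cols if a is not None)
    b_start = next(b for _, b in cols if b is not None)
    if a_start > anchor_slack or b_start > anchor_slack:
        return None
    # trim the chance-match tail the local aligner drags in: keep the
    # best-scoring alignment prefix (a TIR is anchored at the termini)
    best_j, score, best_score = 0, 0.0, -1.0
    matches = cum_matches = 0
    best_matches = 0
    for j, (pa, pb) in enumerate(cols, start=1):
        if pa is None or pb is None:
            score -= 2.5
        elif head[pa] == tail_rc[pb] and head[pa] != "N":
            score += 1.0
            cum_matches += 1
        else:
            score -= 2.0
        if score > best_score:
            best_score, best_j, best_matches = score, j, cum_matches
    cols = cols[:best_j]
    if best_j < min_tir_len:
        return None
    identity = best_matches / best_j
    if identity < min_tir_identity:
        return None
    a_end = max(a for a, _ in cols if a is not None) + 1
    b_end = max(b for _, b in cols if b is not None) + 1
    left = Interval("element", a_start, a_end)
    # positions in tail_rc map back to element coords [L - b_end, L - b_start)
    right = Interval("element", L - b_end, L - b_start)
    if left.end > right.start:  # windows met in the middle: degenerate overlap
        return None
    return TIRPair(left=left, right=right,
                   length=max(len(left), len(right)), identity=identity)


def find_single_tir(
    element_seq: str,
    probe: str,
    min_identity: float = 0.80,
    anchor_slack: int = 5,
) -> Optional[Tuple[str, Interval]]:
    """Locate one TIR by aligning a known TIR probe to either terminus.

    Used for truncated elements where inverted-repeat self-comparison cannot
    work. Returns ("left"|"right", element-local Interval) or None.
    """
    L = len(element_seq)
    w = min(max(4 * len(probe), 60), L)
    aligner = dna_aligner("local")
    candidates = []
    for side, window, win_off in (
        ("left", element_seq[:w], 0),
        ("right", revcomp(element_seq[-w:]), None),
    ):
        alns = aligner.align(window, probe)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        blocks_a, _ = aln.aligned
        if len(blocks_a) == 0:
            continue
        a_start, a_end = blocks_a[0][0], blocks_a[-1][1]
        if a_start > anchor_slack:
            continue
        identity, cols = aligned_identity(aln, window, probe)
        if identity < min_identity or cols < 0.7 * len(probe):
            continue
        if side == "left":
            iv = Interval("element", a_start, a_end)
        else:
            iv = Interval("element", L - a_end, L - a_start)
        candidates.append((aln.score, side, iv))
    if not candidates:
        return None
    _, side, iv = max(candidates, key=lambda c: c[0])
    return side, iv


# ---------------------------------------------------------------------------
# boundary refinement from a multi-copy alignment


def refine_boundaries(
    copies: Sequence[CandidateLocus],
    genome: GenomicSequence,
    identity_threshold: float = 0.7,
    smooth_window: int = 10,
    min_run: int = 20,
) -> Optional[List[Interval]]:
    """Refine element boundaries from the multiple alignment of >= 3 copies.

    Copy-plus-flank sequences are multiply aligned (center-star); the
    boundary is the outermost alignment column where the per-column mean
    pairwise identity, smoothed over ``smooth_window`` columns, exceeds the
    threshold and stays above it for at least ``min_run`` columns. Returns
    one refined genomic Interval per copy, or None (with a warning) when
    refinement is unavailable or finds no identity drop.
    """
    if len(copies) < 3:
        logger.warning("boundary refinement needs >= 3 copies, got %d: "
                       "keeping original intervals", len(copies))
        return None
    seqs, offsets = [], []
    for c in copies:
        iv = c.locus
        start = iv.start - len(c.flank_left)
        seqs.append(c.flank_left + genome.residues[iv.start : iv.end] + c.flank_right)
        offsets.append(start)
    rows = center_star_msa(seqs)
    width = len(rows[0])
    n = len(rows)
    mat = np.frombuffer("".join(rows).encode(), dtype="S1").reshape(n, width)
    npairs = n * (n - 1) // 2
    eq = np.zeros(width)
    for i in range(n):
        for j in range(i + 1, n):
            both = (mat[i] != b"-") & (mat[j] != b"-") & (mat[i] != b"N")
            eq += both & (mat[i] == mat[j])
    identity = eq / npairs
    kernel = np.ones(smooth_window) / smooth_window
    smoothed = np.convolve(identity, kernel, mode="same")
    above = smoothed > identity_threshold
    # left edge: first start of a >= min_run high-identity run
    runs = _runs(above, min_run)
    if not runs:
        logger.warning("boundary refinement found no conserved block")
        return None
    left_col, right_col = runs[0][0], runs[-1][1]
    # the smoothed profile blurs the edge by ~window/2: sharpen against the
    # raw per-column identity
    while left_col > 0 and identity[left_col - 1] > identity_threshold:
        left_col -= 1
    while right_col < width and identity[right_col] > identity_threshold:
        right_col += 1
    if left_col < smooth_window and right_col > width - smooth_window:
        logger.warning("no identity drop at either margin: refinement declines "
                       "(copies may share flanks)")
        return None
    res_left, res_right = [], []
    for i in range(n):
        row = rows[i]
        cum = np.cumsum(np.frombuffer(row.encode(), dtype="S1") != b"-")
        res_left.append(int(cum[left_col - 1]) if left_col > 0 else 0)
        res_right.append(int(cum[right_col - 1]))
    # per-copy edge sharpening: the aligner's edit path can cut the corner at
    # the flank/element junction, scrambling a few edge columns. Anchor on a
    # fully locked column block inside the element and extend outward by
    # pairwise exact matching (median over partners).
    res_left = _sharpen_edges(seqs, res_left, mat, left_col, "left")
    res_right = _sharpen_edges(seqs, res_right, mat, right_col, "right")
    out = []
    for i in range(n):
        start = offsets[i] + res_left[i]
        end = offsets[i] + res_right[i]
        if end <= start:
            logger.warning("refined interval empty for copy %d", i)
            return None
        out.append(Interval(genome.id, start, end))
    return out


def _sharpen_edges(seqs, res_pos, mat, edge_col, side, lock_len=8,
                   max_shift=15):
    n, width = mat.shape
    step = 1 if side == "left" else -1
    col_range = range(edge_col, width - lock_len) if side == "left" \
        else range(min(edge_col, width) - 1, lock_len - 1, -1)
    anchor_col = None
    for c in col_range:
        block = mat[:, c : c + lock_len] if side == "left" \
            else mat[:, c - lock_len + 1 : c + 1]
        if block.shape[1] < lock_len:
            continue
        if (block != b"-").all() and all(
                len(set(block[:, k])) == 1 for k in range(lock_len)):
            anchor_col = c
            break
    if anchor_col is None:
        return res_pos
    # residue index of the anchor column per copy
    anchors = []
    for i in range(n):
        nongap = np.cumsum(mat[i] != b"-")
        anchors.append(int(nongap[anchor_col]) - 1)
    out = []
    for i in range(n):
        exts = []
        for j in range(n):
            if i == j:
                continue
            k = 1
            if side == "left":
                while (anchors[i] - k >= 0 and anchors[j] - k >= 0
                       and seqs[i][anchors[i] - k] == seqs[j][anchors[j] - k]):
                    k += 1
            else:
                while (anchors[i] + k < len(seqs[i])
                       and anchors[j] + k < len(seqs[j])
                       and seqs[i][anchors[i] + k] == seqs[j][anchors[j] + k]):
                    k += 1
            exts.append(k - 1)
        d = int(np.median(exts))
        new = anchors[i] - d if side == "left" else anchors[i] + d + 1
        if abs(new - res_pos[i]) > max_shift:
            out.append(res_pos[i])
        elif side == "left":
            # divergence makes exact extension stop early (inward); the
            # column walk can only drift a base or two outward: keep the
            # outermost of the two estimates
            out.append(min(new, res_pos[i]))
        else:
            out.append(max(new, res_pos[i]))
    return out


def _runs(mask: np.ndarray, min_run: int) -> List[Tuple[int, int]]:
    """Maximal True runs of length >= min_run as (start, end) half-open."""
    runs = []
    start = None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            if i - start >= min_run:
                runs.append((start, i))
            start = None
    if start is not None and len(mask) - start >= min_run:
        runs.append((start, len(mask)))
    return runs


# ---------------------------------------------------------------------------
# boundary polishing (joint TIR + TSD shift search)


def polish_boundaries(
    genome: GenomicSequence,
    coarse: Interval,
    config: Optional[PipelineConfig] = None,
) -> Interval:
    """Shift coarse element ends so TIR and TSD evidence agree.

    Enumerates small shifts of both ends (within ``boundary_polish_slack``)
    and scores each candidate by the mismatch-tolerant inverted-repeat
    extension length at the termini plus a bonus per exactly-duplicated TSD
    base. The TSD term resolves the ambiguity created by (near-)palindromic
    TSDs, which otherwise let the TIR absorb the duplication.
    """
    config = config or PipelineConfig()
    slack = config.boundary_polish_slack
    res = genome.residues
    best = (-1.0, 0, coarse)
    for da in range(-slack, slack + 1):
        a = coarse.start + da
        if a < 2:
            continue
        for db in range(-slack, slack + 1):
            b = coarse.end + db
            if b > len(res) - 2 or b - a < 2 * config.min_tir_len:
                continue
            tir_len = _ir_extension(res, a, b)
            tsd_k = _tsd_k(res, a, b, config.tsd_max_k)
            # the TSD term is capped (real target duplications are 2-4 bp)
            # and canonical TA/TAA/TAAA decompositions get a bonus, else
            # palindromic TSDs and TIR prefixes can absorb each other
            canonical = any(
                res[a - k : a] == res[b : b + k]
                and res[a - k : a] in TSD_CLASSES
                for k in (2, 3, 4) if a - k >= 0 and b + k <= len(res)
            )
            score = tir_len + 3.0 * min(tsd_k, 4) + (10.0 if canonical else 0.0)
            key = (score, -(abs(da) + abs(db)))
            if key > (best[0], best[1]):
                best = (score, -(abs(da) + abs(db)),
                        Interval(coarse.seq_id, a, b, coarse.strand))
    return best[2]


def _ir_extension(res: str, a: int, b: int, cap: int = 80) -> float:
    """Score of the inverted-repeat extension at candidate ends a, b.

    A TIR starts at the element terminus, so the first 4 compared bases
    must match exactly; otherwise the candidate has no TIR evidence (this
    blocks decompositions where a chance direct repeat in the flanks poses
    as a TSD a few bases out).
    """
    if b - a < 8:
        return 0.0
    for k in range(4):
        x = res[a + k]
        y = "TGCA"["ACGT".index(res[b - 1 - k])] if res[b - 1 - k] in "ACGT" else "N"
        if x != y or x == "N":
            return 0.0
    score = best = 0.0
    run = best_run = 0
    for k in range(min(cap, (b - a) // 2)):
        x = res[a + k]
        y = "TGCA"["ACGT".index(res[b - 1 - k])] if res[b - 1 - k] in "ACGT" else "N"
        if x == y and x != "N":
            score += 1.0
            run += 1
        else:
            score -= 2.0
            run = 0
        if score > best:
            best, best_run = score, run
        if best - score > 6:
            break
    return best


def _tsd_k(res: str, a: int, b: int, max_k: int) -> int:
    best = 0
    for k in range(2, max_k + 1):
        if a - k < 0 or b + k > len(res):
            break
        if res[a - k : a] == res[b : b + k]:
            best = k
    return best


# ---------------------------------------------------------------------------
# validation


def validate_element(
    locus: Interval,
    tirs: Optional[TIRPair],
    tsd: Optional[TSDCall],
    tpase: Optional[object],
    config: Optional[PipelineConfig] = None,
) -> AnnotatedElement:
    """Apply the survey's element-validation rule.

    FULL: two TIRs and a TSD. HALF: one TIR, a TSD, and a transposase of at
    least ``min_tpase_aa``. Everything else is DISCARDED with a reason and
    retained in the output.
    """
    config = config or PipelineConfig()
    n_tirs = tirs.n_tirs if tirs is not None else 0
    has_tsd = tsd is not None and tsd.tsd_class != "NONE"
    tpase_aa = len(tpase.protein) if tpase is not None else 0
    if n_tirs == 2 and has_tsd:
        status, reason = "FULL", ""
    elif n_tirs == 1 and has_tsd and tpase_aa >= config.min_tpase_aa:
        status, reason = "HALF", ""
    else:
        status = "DISCARDED"
        bits = []
        if n_tirs < 2:
            bits.append(f"{n_tirs} TIR(s)")
        if not has_tsd:
            bits.append("no TSD")
        if tpase_aa < config.min_tpase_aa:
            bits.append(f"transposase {tpase_aa} aa < {config.min_tpase_aa}")
        reason = "; ".join(bits)
    return AnnotatedElement(locus=locus, tirs=tirs, tsd=tsd, tpase=tpase,
                            status=status, reason=reason)


def annotate_element(
    genome: GenomicSequence,
    coarse: Interval,
    config: Optional[PipelineConfig] = None,
    tir_probe: Optional[str] = None,
) -> AnnotatedElement:
    """Polish one locus and assemble its full structural annotation."""
    from .structure import extract_transposase  # local import: no cycle

    config = config or PipelineConfig()
    locus = polish_boundaries(genome, coarse, config)
    element_seq = genome.residues[locus.start : locus.end]
    tirs = find_tir(element_seq, config.max_tir_len, config.min_tir_len,
                    config.min_tir_identity)
    if tirs is None and tir_probe:
        single = find_single_tir(element_seq, tir_probe,
                                 config.min_tir_identity)
        if single is not None:
            side, iv = single
            if side == "left":
                tirs = TIRPair(left=iv, right=None, length=len(iv), identity=1.0)
            else:
                # keep the detected repeat as the pair's only member
                tirs = TIRPair(left=iv, right=None, length=len(iv), identity=1.0)
    left_flank = genome.residues[max(0, locus.start - config.tsd_max_k) : locus.start]
    right_flank = genome.residues[locus.end : locus.end + config.tsd_max_k]
    tsd = call_tsd(left_flank, right_flank, config.tsd_max_k)
    tpase = extract_transposase(element_seq)
    el = validate_element(locus, tirs, tsd, tpase, config)
    return el
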