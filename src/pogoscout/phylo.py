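"""Catalytic-domain phylogenetics: distances, neighbor joining, bootstrap,
and family assignment against the reference panel.

Neighbor joining (Q-criterion, standard branch lengths, deterministic
lexicographic tie-breaks) is the internal placement engine; alignments can
also be exported in relaxed-PHYLIP and FASTA for external maximum-likelihood
tools, whose inference is deliberately out of scope here.
"""
from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from skbio import DistanceMatrix, TreeNode

from .alignment import aligned_identity, position_map, protein_aligner
from .families import ReferencePanel, load_reference_panel

logger = logging.getLogger(__name__)


@dataclass
class MultipleAlignment:
    """A gapped protein alignment keyed by sequence id."""

    rows: Dict[str, str]

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("an alignment needs at least 2 rows")
        lengths = {len(v) for v in self.rows.values()}
        if len(lengths) != 1:
            raise ValueError("alignment rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values())))

    @property
    def ids(self) -> List[str]:
        return list(self.rows)

    def resample_columns(self, indices: Sequence[int]) -> "MultipleAlignment":
        return MultipleAlignment(rows={
            k: "".join(v[i] for i in indices) for k, v in self.rows.items()
        })


# ---------------------------------------------------------------------------
# domain extraction and panel insertion


def extract_dde_domain(
    protein: str,
    panel: Optional[ReferencePanel] = None,
    min_identity: float = 0.30,
    min_coverage: float = 0.80,
) -> Optional[Tuple[str, Tuple[int, int]]]:
    """Extract the catalytic (DDE) domain of a transposase.

    The protein is aligned to every panel domain; on the best reference the
    aligned query span becomes the domain, provided the alignment covers the
    reference domain, covers all three triad columns, and is similar enough
    to trust. Returns (domain subsequence, (start, end)) in ungapped query
    coordinates, or None.
    """
    panel = panel or load_reference_panel()
    aligner = protein_aligner("local")
    best = None
    for member in panel.members:
        alns = aligner.align(protein, member.domain)
        if len(alns) == 0:
            continue
        if best is None or alns.score > best[0]:
            best = (alns.score, member, alns[0])
    if best is None:
        return None
    _, member, aln = best
    identity, cols = aligned_identity(aln, protein, member.domain)
    if identity < min_identity or cols < min_coverage * len(member.domain):
        return None
    mapping = position_map(aln)
    if any(c not in mapping for c in member.triad_cols):
        return None
    blocks_a, _ = aln.aligned
    qs, qe = blocks_a[0][0], blocks_a[-1][1]
    return protein[qs:qe], (qs, qe)


def _best_reference(query_seq: str, panel: ReferencePanel,
                    allowed: Optional[set] = None):
    """Best-scoring panel member for a query: (score, member, aln, identity)."""
    aligner = protein_aligner("local")
    best = None
    for member in panel.members:
        if allowed is not None and member.id not in allowed:
            continue
        alns = aligner.align(query_seq, member.domain)
        if len(alns) == 0:
            continue
        if best is None or alns.score > best[0]:
            best = (alns.score, member, alns[0])
    if best is None:
        return None
    score, member, aln = best
    identity, cols = aligned_identity(aln, query_seq, member.domain)
    coverage = cols / len(member.domain)
    return score, member, aln, identity, coverage


def panel_alignment(panel: Optional[ReferencePanel] = None) -> MultipleAlignment:
    """The panel as an alignment (members share columns by construction)."""
    panel = panel or load_reference_panel()
    return MultipleAlignment(rows={m.id: m.domain for m in panel.members})


def insert_query(
    aln: MultipleAlignment,
    query_id: str,
    query_seq: str,
    panel: Optional[ReferencePanel] = None,
) -> MultipleAlignment:
    """Profile-insert a query domain into the panel alignment.

    The query is aligned pairwise to its best-matching reference and its
    residues are written into that reference's columns; query residues
    falling between reference columns (insertions) are dropped, unmatched
    columns become gaps.
    """
    panel = panel or load_reference_panel()
    best = _best_reference(query_seq, panel, allowed=set(aln.rows))
    if best is None:
        raise ValueError(f"query {query_id!r} aligns to no panel member")
    _, member, pair = best[:3]
    mapping = position_map(pair)  # member domain pos -> query pos
    row = ["-"] * aln.n_columns
    for dom_pos, q_pos in mapping.items():
        row[dom_pos] = query_seq[q_pos]
    rows = dict(aln.rows)
    rows[query_id] = "".join(row)
    return MultipleAlignment(rows=rows)


# ---------------------------------------------------------------------------
# distances


def pairwise_distance(aln: MultipleAlignment, cap_p: float = 0.99) -> DistanceMatrix:
    """Poisson-corrected p-distances with pairwise gap deletion.

    p is the mismatch fraction over columns where neither row is gapped;
    d = -ln(1 - p); p beyond ``cap_p`` is capped with a warning.
    """
    ids = aln.ids
    arrs = {k: np.frombuffer(v.encode(), dtype="S1") for k, v in aln.rows.items()}
    n = len(ids)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = arrs[ids[i]], arrs[ids[j]]
            shared = (a != b"-") & (b != b"-")
            total = int(shared.sum())
            if total == 0:
                raise ValueError(
                    f"no shared columns between {ids[i]!r} and {ids[j]!r}")
            p = float(((a != b) & shared).sum()) / total
            if p >= cap_p:
                logger.warning("p-distance %.3f capped at %.2f for (%s, %s)",
                               p, cap_p, ids[i], ids[j])
                p = cap_p
            mat[i, j] = mat[j, i] = -np.log(1.0 - p)
    return DistanceMatrix(mat, ids)


# ---------------------------------------------------------------------------
# neighbor joining


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining with deterministic tie-breaks.

    Ties in the Q criterion are broken by the lexicographically smallest
    (label_i, label_j) pair, a node's label being its smallest descendant
    leaf id. Negative branch lengths are clamped to zero with the deficit
    moved to the sister branch. Returns an unrooted tree (trifurcating root).
    """
    ids = list(dm.ids)
    if len(ids) < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    if not np.allclose(dm.data, dm.data.T, atol=1e-12):
        raise ValueError("distance matrix is not symmetric")
    nodes: Dict[str, TreeNode] = {i: TreeNode(name=i) for i in ids}
    labels = {i: i for i in ids}
    d = {frozenset((a, b)): dm[a, b] for a in ids for b in ids if a != b}
    active = sorted(ids)
    counter = 0
    while len(active) > 3:
        n = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a)
             for a in active}
        best = None
        for x in range(n):
            for y in range(x + 1, n):
                a, b = active[x], active[y]
                q = (n - 2) * d[frozenset((a, b))] - r[a] - r[b]
                pair_label = tuple(sorted((labels[a], labels[b])))
                key = (q, pair_label)
                if best is None or key < best[0]:
                    best = (key, a, b)
        _, a, b = best
        dab = d[frozenset((a, b))]
        la = dab / 2 + (r[a] - r[b]) / (2 * (n - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        elif lb < 0:
            la, lb = dab, 0.0
        counter += 1
        u = f"__nj{counter}"
        na, nb = nodes.pop(a), nodes.pop(b)
        na.length, nb.length = float(la), float(lb)
        nodes[u] = TreeNode(children=[na, nb])
        labels[u] = min(labels[a], labels[b])
        for c in active:
            if c in (a, b):
                continue
            duc = (d[frozenset((a, c))] + d[frozenset((b, c))] - dab) / 2
            d[frozenset((u, c))] = max(duc, 0.0)
        active = sorted((set(active) - {a, b}) | {u}, key=lambda k: labels[k])
    a, b, c = sorted(active, key=lambda k: labels[k])
    dab, dac, dbc = (d[frozenset((a, b))], d[frozenset((a, c))],
                     d[frozenset((b, c))])
    la = (dab + dac - dbc) / 2
    lb = (dab + dbc - dac) / 2
    lc = (dac + dbc - dab) / 2
    root_children = []
    for name, length in ((a, la), (b, lb), (c, lc)):
        node = nodes.pop(name)
        node.length = float(max(length, 0.0))
        root_children.append(node)
    return TreeNode(children=root_children)


def tree_bipartitions(tree: TreeNode) -> List[frozenset]:
    """Non-trivial bipartitions as frozensets of the side not containing the
    lexicographically smallest tip (canonical orientation)."""
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    universe = set(tips)
    out = []
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if ref in side:
            side = universe - side
        out.append(frozenset(side))
    return out


def bootstrap_support(
    aln: MultipleAlignment,
    n_reps: int = 1000,
    seed: int = 0,
) -> TreeNode:
    """NJ tree with classical bootstrap supports on internal nodes.

    Columns are resampled with replacement per replicate (one canonical
    column sample per replicate, independent of taxon order); support is the
    percentage of replicate trees containing each original bipartition,
    written into node.support and the internal-node name.
    """
    if len(aln.rows) < 4:
        raise ValueError("bootstrap needs at least 4 rows")
    tree = neighbor_joining(pairwise_distance(aln))
    if n_reps <= 0:
        return tree
    rng = np.random.default_rng(seed)
    counts: Dict[frozenset, int] = {}
    for _ in range(n_reps):
        idx = rng.integers(aln.n_columns, size=aln.n_columns)
        rep_tree = neighbor_joining(pairwise_distance(aln.resample_columns(idx)))
        for bip in set(tree_bipartitions(rep_tree)):
            counts[bip] = counts.get(bip, 0) + 1
    tips = sorted(t.name for t in tree.tips())
    ref = tips[0]
    universe = set(tips)
    for node in tree.non_tips(include_self=False):
        side = {t.name for t in node.tips()}
        if len(side) < 2 or len(side) > len(tips) - 2:
            continue
        if ref in side:
            side = universe - side
        support = 100.0 * counts.get(frozenset(side), 0) / n_reps
        node.support = support
        node.name = f"{support:.0f}"
    return tree


# ---------------------------------------------------------------------------
# family assignment


@dataclass(frozen=True)
class FamilyAssignment:
    query_id: str
    family: str     # one of the panel families, or "Unclassified"
    support: float  # percent of replicates placing the query in that clade

    def __post_init__(self):
        if not (0.0 <= self.support <= 100.0):
            raise ValueError("support must lie in [0, 100]")


def assign_family(
    query_domains: Dict[str, str],
    panel: Optional[ReferencePanel] = None,
    n_reps: int = 200,
    seed: int = 0,
    threshold: float = 50.0,
    min_identity: float = 0.30,
) -> List[FamilyAssignment]:
    """Place query catalytic domains onto the reference panel.

    Each query is profile-inserted into the panel alignment; bootstrap NJ
    replicates are computed; the query's family is the reference clade whose
    members plus the query form a bipartition in the largest fraction of
    replicates. Below ``threshold`` percent the query stays Unclassified.
    """
    panel = panel or load_reference_panel()
    for fam in panel.families():
        if len(panel.by_family(fam)) < 2:
            raise ValueError(f"panel family {fam!r} has fewer than 2 members")
    base = panel_alignment(panel)
    fam_members = {f: frozenset(m.id for m in panel.by_family(f))
                   for f in panel.families()}
    out = []
    for qid in sorted(query_domains):
        gate = _best_reference(query_domains[qid], panel)
        if gate is None or gate[3] < min_identity or gate[4] < 0.6:
            # no credible homology to any reference: placement is meaningless
            out.append(FamilyAssignment(qid, "Unclassified", 0.0))
            continue
        aln = insert_query(base, qid, query_domains[qid], panel)
        rng = np.random.default_rng([seed, zlib.crc32(qid.encode()) % (2**31)])
        votes = {f: 0 for f in fam_members}
        for _ in range(n_reps):
            idx = rng.integers(aln.n_columns, size=aln.n_columns)
            rep_tree = neighbor_joining(pairwise_distance(aln.resample_columns(idx)))
            bips = set(tree_bipartitions(rep_tree))
            # also admit clade = whole side when reading from the other end
            sides = bips | {frozenset(set(aln.ids) - b) for b in bips}
            for f, members in fam_members.items():
                if frozenset(members | {qid}) in sides:
                    votes[f] += 1
        fam, n_votes = max(votes.items(), key=lambda kv: (kv[1], kv[0]))
        support = 100.0 * n_votes / n_reps if n_reps else 0.0
        if support < threshold:
            out.append(FamilyAssignment(qid, "Unclassified", support))
        else:
            out.append(FamilyAssignment(qid, fam, support))
    return out


# ---------------------------------------------------------------------------
# export


def export_ml_alignment(aln: MultipleAlignment, phylip_path,
                        fasta_path=None) -> None:
    """Write the alignment in relaxed PHYLIP (ids of any length) and FASTA,
    ready for external maximum-likelihood tools."""
    ids = aln.ids
    with open(phylip_path, "w") as fh:
        fh.write(f"{len(ids)} {aln.n_columns}\n")
        width = max(len(i) for i in ids) + 2
        for i in ids:
            fh.write(i.ljust(width) + aln.rows[i] + "\n")
    if fasta_path is not None:
        with open(fasta_path, "w") as fh:
            for i in ids:
                fh.write(f">{i}\n{aln.rows[i]}\n")
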