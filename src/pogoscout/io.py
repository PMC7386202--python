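"""Readers and writers for the standard formats the pipeline touches.

FASTA goes through Biopython, newick through scikit-bio; the 12-column tabular
hit dialect (qseqid sseqid pident length mismatch gapopen qstart qend sstart
send evalue bitscore) and the per-domain table dialect (domtblout) are parsed
here because their coordinate conventions need normalising to the package's
0-based half-open Intervals.
"""
from __future__ import annotations

import io as _io
from typing import Iterable, Optional, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio import TreeNode

from .config import PipelineConfig
from .model import DNA_ALPHABET, GenomicSequence, HitRecord, Interval


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


def read_fasta(path, dna: bool = True) -> list:
    """Read a FASTA file.

    In DNA mode returns :class:`GenomicSequence` records (U mapped to T,
    alphabet checked); otherwise returns ``(id, residues)`` tuples for
    protein sequences. Record order is preserved.
    """
    records = []
    seen = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if dna:
            residues = residues.replace("U", "T")
            bad = set(residues) - DNA_ALPHABET
            if bad:
                raise FormatError(
                    f"{path}: record {rec.id!r} has illegal DNA characters "
                    f"{sorted(bad)}"
                )
            records.append(GenomicSequence(id=rec.id, residues=residues))
        else:
            records.append((rec.id, residues))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path, width: int = 70) -> None:
    """Write GenomicSequence records or (id, residues) tuples as FASTA."""
    seqrecs = []
    for rec in records:
        if isinstance(rec, GenomicSequence):
            rid, residues = rec.id, rec.residues
        else:
            rid, residues = rec
        seqrecs.append(SeqRecord(Seq(residues), id=rid, description=""))
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqrecs)


def read_tabular_hits(path, config: Optional[PipelineConfig] = None) -> list:
    """Parse 12-column tabular hits, filter by e-value, normalise strand.

    Subject coordinates given as sstart > send encode a minus-strand hit; the
    stored Interval always has start < end (0-based half-open). Percent
    identity on the file's 0-100 scale is divided by 100. Rows with e-value
    above ``config.evalue_cutoff`` are dropped.
    """
    config = config or PipelineConfig()
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 12:
                raise FormatError(
                    f"{path}:{lineno}: expected 12 tab-separated columns, "
                    f"got {len(cols)}"
                )
            try:
                qseqid, sseqid = cols[0], cols[1]
                pident = float(cols[2])
                length = int(cols[3])
                sstart, send = int(cols[8]), int(cols[9])
                evalue = float(cols[10])
                bitscore = float(cols[11])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric column: {exc}")
            if evalue > config.evalue_cutoff:
                continue
            if sstart <= send:
                strand, lo, hi = "+", sstart, send
            else:
                strand, lo, hi = "-", send, sstart
            target = Interval(seq_id=sseqid, start=lo - 1, end=hi, strand=strand)
            hits.append(
                HitRecord(
                    query_id=qseqid,
                    target=target,
                    percent_identity=pident / 100.0,
                    alignment_length=length,
                    evalue=evalue,
                    bit_score=bitscore,
                )
            )
    return hits


def read_domtbl(path, evalue_cutoff: float = 1e-5) -> list:
    """Parse a per-domain tabular hit file (domtblout dialect).

    Returns ``(target_name, query_name, i_evalue, ali_from, ali_to, score)``
    tuples with alignment coordinates converted to 0-based half-open on the
    query protein; domains with independent e-value above the cutoff dropped.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) < 22:
                raise FormatError(
                    f"{path}:{lineno}: expected >=22 whitespace columns"
                )
            try:
                target_name = cols[0]
                query_name = cols[3]
                i_evalue = float(cols[12])
                score = float(cols[13])
                ali_from, ali_to = int(cols[17]), int(cols[18])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad column: {exc}")
            if i_evalue > evalue_cutoff:
                continue
            rows.append((target_name, query_name, i_evalue, ali_from - 1, ali_to, score))
    return rows


# ---------------------------------------------------------------------------
# GFF3


def write_gff3(elements, path) -> None:
    """Write annotated elements as GFF3 (1-based inclusive coordinates).

    Each element becomes a ``transposable_element`` feature with TIR, TSD and
    ORF child features where present.
    """
    from .boundary import AnnotatedElement  # local import: avoid cycle

    lines = ["##gff-version 3"]
    for i, el in enumerate(elements):
        if isinstance(el, AnnotatedElement):
            eid = el.id or f"element_{i + 1}"
            lines.extend(_element_gff3_lines(el, eid))
        else:  # bare Interval
            eid = f"element_{i + 1}"
            lines.append(_gff3_line(el, "transposable_element", f"ID={eid}"))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def _gff3_line(iv: Interval, ftype: str, attrs: str, score: str = ".") -> str:
    return "\t".join(
        [iv.seq_id, "pogoscout", ftype, str(iv.start + 1), str(iv.end),
         score, iv.strand, ".", attrs]
    )


def _element_gff3_lines(el, eid: str) -> list:
    lines = [_gff3_line(el.locus, "transposable_element",
                        f"ID={eid};status={el.status}")]
    if el.tirs is not None:
        lines.append(_gff3_line(el.tirs.left, "terminal_inverted_repeat",
                                f"Parent={eid};side=left"))
        if el.tirs.right is not None:
            lines.append(_gff3_line(el.tirs.right, "terminal_inverted_repeat",
                                    f"Parent={eid};side=right"))
    if el.tsd is not None and el.tsd.repeat:
        lines.append(
            "\t".join([el.locus.seq_id, "pogoscout", "target_site_duplication",
                       ".", ".", ".", el.locus.strand, ".",
                       f"Parent={eid};repeat={el.tsd.repeat};class={el.tsd.tsd_class}"])
        )
    if el.tpase is not None:
        lines.append(_gff3_line(el.tpase.orf, "ORF",
                                f"Parent={eid};aa={len(el.tpase.protein)}"))
    return lines


def read_gff3_intervals(path) -> list:
    """Read top-level feature Intervals back from a GFF3 file."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF3 columns")
            if cols[3] == ".":
                continue
            try:
                start, end = int(cols[3]), int(cols[4])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: bad coordinate: {exc}")
            out.append(Interval(seq_id=cols[0], start=start - 1, end=end,
                                strand=cols[6] if cols[6] in "+-" else "+"))
    return out


# ---------------------------------------------------------------------------
# Trees and reports


def write_newick(tree: TreeNode, path) -> None:
    """Write a tree as newick with branch lengths and internal-node labels."""
    tree.write(str(path), format="newick")


def read_newick(path) -> TreeNode:
    return TreeNode.read(str(path), format="newick")


def write_tsv_report(records: Iterable[dict], path,
                     columns: Optional[Sequence[str]] = None) -> None:
    """Write dict records as a TSV with a documented header line."""
    records = list(records)
    if columns is None:
        columns = list(records[0].keys()) if records else []
    buf = _io.StringIO()
    buf.write("# " + "\t".join(columns) + "\n")
    buf.write("\t".join(columns) + "\n")
    for rec in records:
        buf.write("\t".join(str(rec.get(c, "")) for c in columns) + "\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())
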