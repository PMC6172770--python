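"""Readers and writers for the standard formats the pipeline touches.

FASTA via Biopython, SAM via pysam, BLAST-tabular and TSV matrices via
pandas.  Coordinates are 0-based half-open internally; 1-based formats
(SAM) are converted at the parser boundary.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .abundance import AlignmentRecord

BLAST_TAB_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class ParseError(ValueError):
    pass


def read_fasta(path: str | Path) -> dict[str, str]:
    """FASTA to an ordered {id: sequence} dict; empty records are rejected."""
    records: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in records:
            raise ParseError(f"{path}: duplicate record id {rec.id!r}")
        records[rec.id] = str(rec.seq).upper()
    for rid, seq in records.items():
        if not seq:
            line = _find_header_line(path, rid)
            raise ParseError(f"{path}: record {rid!r} has no sequence (line {line})")
    return records


def _find_header_line(path: str | Path, rid: str) -> int:
    with open(path) as fh:
        for i, line in enumerate(fh, start=1):
            if line.startswith(">") and line[1:].split()[0] == rid:
                return i
    return -1


def write_fasta(records: Mapping[str, str], path: str | Path, width: int = 70) -> None:
    seqs = [SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Parse SAM alignments into AlignmentRecords.

    aligned_len is the number of read bases in aligned columns
    (CIGAR M/=/X plus I); matches are derived from the NM tag:
    matches = (M + = + X) - (NM - inserted - deleted).  Unmapped and
    secondary records are skipped.
    """
    out: list[AlignmentRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for i, aln in enumerate(sam):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            stats = {op: 0 for op in "MIDNSHP=X"}
            for op, length in aln.cigartuples or []:
                stats["MIDNSHP=X"[op]] += length
            mx = stats["M"] + stats["="] + stats["X"]
            aligned_len = mx + stats["I"]
            try:
                nm = aln.get_tag("NM")
            except KeyError:
                raise ParseError(f"{path}: record {i} ({aln.query_name}) lacks an NM tag")
            matches = mx - (int(nm) - stats["I"] - stats["D"])
            read_len = aln.query_length or aligned_len
            rec = AlignmentRecord(
                read_id=aln.query_name,
                contig_id=aln.reference_name,
                read_len=read_len,
                aligned_len=aligned_len,
                matches=matches,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
            )
            try:
                rec.validate()
            except ValueError as exc:
                raise ParseError(f"{path}: record {i}: {exc}") from exc
            out.append(rec)
    return out


def read_blast_tab(
    path: str | Path, columns: Sequence[str] = BLAST_TAB_COLUMNS
) -> pd.DataFrame:
    """BLAST tabular (outfmt-6-like) with a configurable column order."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] != len(columns):
        raise ParseError(
            f"{path}: expected {len(columns)} columns ({' '.join(columns)}), "
            f"found {df.shape[1]}"
        )
    df.columns = list(columns)
    return df


def blast_tab_to_alignments(df: pd.DataFrame, query_lengths: Mapping[str, int] | None = None) -> list[AlignmentRecord]:
    """Convert BLAST-tabular hits to AlignmentRecords (1-based to half-open)."""
    out = []
    for _, row in df.iterrows():
        length = int(row["length"])
        matches = int(round(float(row["pident"]) / 100 * length))
        s, e = int(row["sstart"]), int(row["send"])
        strand = "+" if e >= s else "-"
        lo, hi = (s - 1, e) if strand == "+" else (e - 1, s)
        qlen = query_lengths.get(row["qseqid"], length) if query_lengths else length
        out.append(
            AlignmentRecord(
                read_id=str(row["qseqid"]),
                contig_id=str(row["sseqid"]),
                read_len=max(qlen, length),
                aligned_len=length,
                matches=matches,
                start=lo,
                end=hi,
                strand=strand,
            )
        )
    return out


def read_tsv_matrix(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_tsv_matrix(matrix: pd.DataFrame, path: str | Path, float_format: str = "%.10g") -> None:
    matrix.to_csv(path, sep="\t", float_format=float_format)


def write_alignments_tsv(records: Sequence[AlignmentRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            (r.read_id, r.contig_id, r.read_len, r.aligned_len, r.matches, r.start, r.end, r.strand)
            for r in records
        ],
        columns=["read_id", "contig_id", "read_len", "aligned_len", "matches", "start", "end", "strand"],
    ).to_csv(path, sep="\t", index=False)


def read_alignments_tsv(path: str | Path) -> list[AlignmentRecord]:
    df = pd.read_csv(path, sep="\t")
    return [
        AlignmentRecord(
            read_id=str(r.read_id),
            contig_id=str(r.contig_id),
            read_len=int(r.read_len),
            aligned_len=int(r.aligned_len),
            matches=int(r.matches),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
        )
        for r in df.itertuples()
    ]
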