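"""Read-recruitment detection and abundance quantification of vOTUs.

A read counts toward a contig only if its alignment identity reaches 90%,
and a contig counts as detected in a sample only if mapped reads cover at
least 75% of its length (breadth of coverage).  Abundance is mapped base
pairs, normalised by contig length and library size, reported per Gbp of
library so values sit in a convenient O(1-100) range.  Undetected cells
are reported as zero abundance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

PER_GBP = 1e9  # scaling constant: abundances are reported per Gbp of library


@dataclass(frozen=True)
class AlignmentRecord:
    """One read-to-contig alignment (0-based half-open contig coordinates)."""

    read_id: str
    contig_id: str
    read_len: int
    aligned_len: int
    matches: int
    start: int
    end: int
    strand: str = "+"

    def validate(self) -> None:
        if not (0 <= self.matches <= self.aligned_len <= self.read_len):
            raise ValueError(
                f"read {self.read_id!r}: require 0 <= matches <= aligned_len <= read_len "
                f"(got {self.matches}, {self.aligned_len}, {self.read_len})"
            )
        if not self.start < self.end:
            raise ValueError(f"read {self.read_id!r}: start must be < end")

    @property
    def identity(self) -> float:
        return self.matches / self.aligned_len if self.aligned_len else 0.0


def filter_alignments(
    alignments: Sequence[AlignmentRecord], min_read_ani: float = 0.90
) -> list[AlignmentRecord]:
    """Identity filter plus best-hit-per-read selection.

    Retains records with matches / aligned_len >= ``min_read_ani``, then
    keeps only each read's best-scoring record (most matches; ties go to
    the earliest record in input order).
    """
    best: dict[str, AlignmentRecord] = {}
    order: list[str] = []
    for i, rec in enumerate(alignments):
        try:
            rec.validate()
        except ValueError as exc:
            raise ValueError(f"malformed alignment record at index {i}: {exc}") from exc
        if rec.identity < min_read_ani:
            continue
        prev = best.get(rec.read_id)
        if prev is None:
            best[rec.read_id] = rec
            order.append(rec.read_id)
        elif rec.matches > prev.matches:
            best[rec.read_id] = rec
    return [best[r] for r in order]


@dataclass
class SampleQuant:
    """Detection and abundance for one sample (one abundance-matrix row)."""

    abundance: pd.Series  # per-Gbp normalised abundance, zeroed when undetected
    breadth: pd.Series  # covered fraction of each contig
    detected: pd.Series  # breadth >= min_breadth
    mapped_bp: pd.Series


def _union_covered(intervals: list[tuple[int, int]]) -> int:
    """Total length of the union of half-open intervals (no double counting)."""
    if not intervals:
        return 0
    intervals.sort()
    total = 0
    lo, hi = intervals[0]
    for s, e in intervals[1:]:
        if s > hi:
            total += hi - lo
            lo, hi = s, e
        else:
            hi = max(hi, e)
    return total + (hi - lo)


def detect_and_quantify(
    alignments: Sequence[AlignmentRecord],
    contig_lengths: Mapping[str, int],
    total_bp: int,
    min_breadth: float = 0.75,
) -> SampleQuant:
    """Breadth-gated, length- and library-normalised abundance for one sample.

    ``alignments`` must already be identity-filtered.  Breadth is the union
    of covered intervals over the contig length; abundance is
    (mapped bp / contig length) / total_bp * 1e9.  Contigs failing the
    breadth threshold get abundance 0 and detected=False.
    """
    if total_bp <= 0:
        raise ValueError("total_bp must be positive")
    contigs = sorted(contig_lengths)
    by_contig: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}
    bp: dict[str, int] = {c: 0 for c in contigs}
    for rec in alignments:
        if rec.contig_id not in contig_lengths:
            raise KeyError(f"contig {rec.contig_id!r} missing from the length table")
        if rec.end > contig_lengths[rec.contig_id]:
            raise ValueError(f"read {rec.read_id!r} extends past contig end")
        by_contig[rec.contig_id].append((rec.start, rec.end))
        bp[rec.contig_id] += rec.aligned_len

    breadth = pd.Series(
        {c: _union_covered(by_contig[c]) / contig_lengths[c] for c in contigs}, dtype=float
    )
    mapped = pd.Series(bp, dtype=float)
    abundance = (mapped / pd.Series(contig_lengths, dtype=float)) / total_bp * PER_GBP
    detected = breadth >= min_breadth
    abundance[~detected] = 0.0
    return SampleQuant(
        abundance=abundance, breadth=breadth, detected=detected, mapped_bp=mapped
    )


@dataclass
class AbundanceMatrix:
    """Samples x vOTUs abundances with detection flags and breadth."""

    values: pd.DataFrame
    detected: pd.DataFrame
    breadth: pd.DataFrame

    @classmethod
    def from_samples(cls, rows: Mapping[str, SampleQuant]) -> "AbundanceMatrix":
        samples = list(rows)
        return cls(
            values=pd.DataFrame({s: rows[s].abundance for s in samples}).T,
            detected=pd.DataFrame({s: rows[s].detected for s in samples}).T,
            breadth=pd.DataFrame({s: rows[s].breadth for s in samples}).T,
        )


def total_sum_scale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample row by its row sum (total-sum scaling).

    All-zero rows are left as zeros with a warning; negative values raise.
    """
    if (matrix.values < 0).any():
        raise ValueError("total_sum_scale requires non-negative values")
    sums = matrix.sum(axis=1)
    zero = sums == 0
    if zero.any():
        warnings.warn(f"all-zero rows left unscaled: {list(matrix.index[zero])}")
    safe = sums.where(~zero, 1.0)
    return matrix.div(safe, axis=0)


# ---------------------------------------------------------------------------
# per-virome read-count summaries


@dataclass
class ViromeSummary:
    """Read-count bookkeeping for one virome (library)."""

    sample: str
    total_reads: int
    assembled_reads: int
    viral_reads: int
    votu_reads: int

    def validate(self) -> None:
        ok = 0 <= self.votu_reads <= self.viral_reads <= self.assembled_reads <= self.total_reads
        if not ok:
            raise ValueError(
                f"{self.sample}: require votu <= viral <= assembled <= total reads "
                f"(got {self.votu_reads}, {self.viral_reads}, "
                f"{self.assembled_reads}, {self.total_reads})"
            )


@dataclass
class ViromeStats:
    """Derived statistics over a set of viromes."""

    per_sample: pd.DataFrame  # adds assembled_pct, viral_pct, votu_pct columns
    mean_assembled_pct: float
    min_assembled_pct: float
    max_assembled_pct: float
    pooled_votu_of_assembled_pct: float
    pooled_votu_of_viral_pct: float

    def fold_ratio(self, sample_a: str, sample_b: str, column: str = "assembled_reads") -> float:
        """Ratio of a count column between two named samples (a / b)."""
        return float(self.per_sample.loc[sample_a, column] / self.per_sample.loc[sample_b, column])


def summarize_viromes(table: Iterable[ViromeSummary] | pd.DataFrame) -> ViromeStats:
    """Per-sample assembly percentages and pooled vOTU read fractions.

    Accepts ViromeSummary records or a DataFrame indexed by sample with
    columns total_reads / assembled_reads / viral_reads / votu_reads.
    """
    if isinstance(table, pd.DataFrame):
        summaries = [
            ViromeSummary(
                sample=str(idx),
                total_reads=int(row["total_reads"]),
                assembled_reads=int(row["assembled_reads"]),
                viral_reads=int(row["viral_reads"]),
                votu_reads=int(row["votu_reads"]),
            )
            for idx, row in table.iterrows()
        ]
    else:
        summaries = list(table)
    if not summaries:
        raise ValueError("no virome summaries supplied")
    for s in summaries:
        s.validate()

    df = pd.DataFrame(
        {
            "total_reads": [s.total_reads for s in summaries],
            "assembled_reads": [s.assembled_reads for s in summaries],
            "viral_reads": [s.viral_reads for s in summaries],
            "votu_reads": [s.votu_reads for s in summaries],
        },
        index=[s.sample for s in summaries],
    )
    df["assembled_pct"] = df.assembled_reads / df.total_reads * 100
    df["viral_pct_of_assembled"] = df.viral_reads / df.assembled_reads * 100
    df["votu_pct_of_assembled"] = df.votu_reads / df.assembled_reads * 100

    pooled_assembled = df.assembled_reads.sum()
    pooled_viral = df.viral_reads.sum()
    pooled_votu = df.votu_reads.sum()
    return ViromeStats(
        per_sample=df,
        mean_assembled_pct=float(df.assembled_pct.mean()),
        min_assembled_pct=float(df.assembled_pct.min()),
        max_assembled_pct=float(df.assembled_pct.max()),
        pooled_votu_of_assembled_pct=float(pooled_votu / pooled_assembled * 100),
        pooled_votu_of_viral_pct=float(pooled_votu / pooled_viral * 100),
    )


def spearman_rank_agreement(estimated: pd.Series, truth: pd.Series) -> float:
    """Spearman correlation between estimated and true abundances (shared index)."""
    from scipy.stats import spearmanr

    common = estimated.index.intersection(truth.index)
    rho, _ = spearmanr(estimated[common], truth[common])
    return float(rho)
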