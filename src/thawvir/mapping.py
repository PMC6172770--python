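"""Minimal k-mer-seeded read mapper for the synthetic test path.

Not a production aligner: it exists so the synthetic pipeline can recruit
reads to vOTU representatives without external tools.  Reads are seeded
with exact k-mers against an index of the reference contigs, candidate
(contig, diagonal) placements are voted on, and the best candidates are
verified with a semi-global edlib alignment that consumes the whole read.
External SAM or BLAST-tabular alignments can be used instead via
:mod:`thawvir.io`.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Mapping

import edlib

from ._align import _count_matches, revcomp
from .abundance import AlignmentRecord


class ReadMapper:
    def __init__(
        self,
        contigs: Mapping[str, str],
        k: int = 17,
        max_kmer_hits: int = 50,
        n_seeds: int = 6,
        diag_bucket: int = 16,
    ):
        self.contigs = dict(contigs)
        self.k = k
        self.n_seeds = n_seeds
        self.diag_bucket = diag_bucket
        index: dict[str, list[tuple[str, int]]] = {}
        for cid in sorted(self.contigs):
            seq = self.contigs[cid]
            for i in range(len(seq) - k + 1):
                index.setdefault(seq[i : i + k], []).append((cid, i))
        self.index = {km: hits for km, hits in index.items() if len(hits) <= max_kmer_hits}

    def _candidates(self, seq: str) -> Counter:
        k = self.k
        span = len(seq) - k
        if span < 0:
            return Counter()
        stride = max(1, span // max(1, self.n_seeds - 1)) if span else 1
        votes: Counter = Counter()
        for qi in range(0, span + 1, stride):
            hits = self.index.get(seq[qi : qi + k])
            if hits:
                for cid, ti in hits:
                    votes[(cid, (ti - qi) // self.diag_bucket)] += 1
        return votes

    def map_read(self, read_id: str, seq: str) -> AlignmentRecord | None:
        """Best alignment of one read, or None when unmapped."""
        best: AlignmentRecord | None = None
        for strand, oriented in (("+", seq), ("-", revcomp(seq))):
            votes = self._candidates(oriented)
            for (cid, bucket), _ in votes.most_common(2):
                target = self.contigs[cid]
                diag = bucket * self.diag_bucket
                lo = max(0, diag - 8)
                hi = min(len(target), diag + len(oriented) + self.diag_bucket + 8)
                window = target[lo:hi]
                res = edlib.align(oriented, window, mode="HW", task="path")
                if res["editDistance"] < 0 or not res["locations"]:
                    continue
                nice = edlib.getNiceAlignment(res, oriented, window)
                matches, _ = _count_matches(nice["query_aligned"], nice["target_aligned"])
                loc = res["locations"][0]
                rec = AlignmentRecord(
                    read_id=read_id,
                    contig_id=cid,
                    read_len=len(seq),
                    aligned_len=len(seq),
                    matches=matches,
                    start=lo + loc[0],
                    end=lo + loc[1] + 1,
                    strand=strand,
                )
                if best is None or rec.matches > best.matches:
                    best = rec
        return best

    def map_reads(self, reads: Iterable[tuple[str, str]]) -> list[AlignmentRecord]:
        """Map a collection of (read_id, sequence) pairs; unmapped reads are dropped."""
        out = []
        for rid, seq in reads:
            rec = self.map_read(rid, seq)
            if rec is not None:
                out.append(rec)
        return out
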