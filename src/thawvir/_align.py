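"""Shared k-mer-anchored local alignment engine.

Exact k-mers anchor candidate homologous segments; anchors are grouped into
near-diagonal clusters and each cluster window is aligned with edlib
(banded bit-parallel edit distance).  Two random nucleotide sequences share
essentially no long k-mers, so unrelated pairs are rejected without any
dynamic-programming work -- which is also what makes "no qualifying
alignment" a meaningful outcome for ANI-style comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib

_ACGT = frozenset("ACGT")
_RC = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement (A/C/G/T/N alphabet)."""
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class LocalAlignment:
    """One aligned segment between a query and a target sequence.

    Coordinates are 0-based half-open.  ``columns`` counts all alignment
    columns including gap columns; ``matches`` counts columns where both
    characters are identical and in {A,C,G,T} (N never matches).
    """

    q_start: int
    q_end: int
    t_start: int
    t_end: int
    matches: int
    columns: int

    @property
    def identity(self) -> float:
        return self.matches / self.columns if self.columns else 0.0


class KmerIndex:
    """Position index of all k-mers of a target sequence."""

    def __init__(self, seq: str, k: int, max_positions: int = 100):
        self.seq = seq
        self.k = k
        index: dict[str, list[int]] = {}
        for i in range(len(seq) - k + 1):
            index.setdefault(seq[i : i + k], []).append(i)
        # drop hyper-repetitive k-mers (uninformative anchors)
        self.index = {km: pos for km, pos in index.items() if len(pos) <= max_positions}

    def anchors(self, query: str, stride: int = 1) -> list[tuple[int, int]]:
        """(query_pos, target_pos) pairs of shared k-mers, scanned left-to-right."""
        k, idx = self.k, self.index
        out = []
        for qi in range(0, len(query) - k + 1, stride):
            hits = idx.get(query[qi : qi + k])
            if hits:
                for ti in hits:
                    out.append((qi, ti))
        return out


def _cluster_anchors(
    anchors: list[tuple[int, int]], k: int, band: int = 32, max_gap: int = 400
) -> list[tuple[int, int, int, int, int]]:
    """Group anchors into near-diagonal clusters.

    Returns (q_lo, q_hi, t_lo, t_hi, n_anchors) spans (half-open, k included).
    Anchors join a cluster when their diagonal is within ``band`` of the
    cluster diagonal and the along-query gap is below ``max_gap``.
    """
    if not anchors:
        return []
    anchors = sorted(anchors, key=lambda a: (a[0] - a[1], a[0]))
    clusters = []
    q0, t0 = anchors[0]
    cur = [q0, q0 + k, t0, t0 + k, 1]
    cur_diag = q0 - t0
    last_q = q0
    for q, t in anchors[1:]:
        d = q - t
        if abs(d - cur_diag) <= band and abs(q - last_q) <= max_gap:
            cur[0] = min(cur[0], q)
            cur[1] = max(cur[1], q + k)
            cur[2] = min(cur[2], t)
            cur[3] = max(cur[3], t + k)
            cur[4] += 1
        else:
            clusters.append(tuple(cur))
            cur = [q, q + k, t, t + k, 1]
            cur_diag = d
        last_q = q
    clusters.append(tuple(cur))
    return clusters


def _count_matches(query_aln: str, target_aln: str) -> tuple[int, int]:
    """(matches, columns) over an aligned pair of gapped strings."""
    matches = 0
    for qc, tc in zip(query_aln, target_aln):
        if qc == tc and qc in _ACGT:
            matches += 1
    return matches, len(query_aln)


def _align_window(
    query: str, target: str, q_lo: int, q_hi: int, t_lo: int, t_hi: int, pad: int
) -> LocalAlignment | None:
    """Align a query window inside a (wider) target window with edlib.

    The query window is consumed end-to-end (semi-global), so end gaps on the
    target side are free; this keeps edge effects out of the identity.
    """
    q_lo, q_hi = max(0, q_lo), min(len(query), q_hi)
    t_lo = max(0, t_lo - pad)
    t_hi = min(len(target), t_hi + pad)
    qwin = query[q_lo:q_hi]
    twin = target[t_lo:t_hi]
    if not qwin or not twin:
        return None
    res = edlib.align(qwin, twin, mode="HW", task="path")
    if res["editDistance"] < 0 or not res["locations"]:
        return None
    loc = res["locations"][0]
    nice = edlib.getNiceAlignment(res, qwin, twin)
    matches, columns = _count_matches(nice["query_aligned"], nice["target_aligned"])
    return LocalAlignment(
        q_start=q_lo,
        q_end=q_hi,
        t_start=t_lo + loc[0],
        t_end=t_lo + loc[1] + 1,
        matches=matches,
        columns=columns,
    )


def local_alignments(
    query: str,
    target: str,
    k: int = 13,
    min_anchors: int = 1,
    band: int = 32,
    max_gap: int = 400,
    index: "KmerIndex | None" = None,
) -> list[LocalAlignment]:
    """All anchored local alignments between two sequences (forward strand).

    Returns an empty list when the sequences share no informative k-mers,
    which is the expected outcome for unrelated random sequences.
    """
    if index is None:
        index = KmerIndex(target, k)
    anchors = index.anchors(query)
    out = []
    for q_lo, q_hi, t_lo, t_hi, n in _cluster_anchors(anchors, k, band, max_gap):
        if n < min_anchors:
            continue
        aln = _align_window(query, target, q_lo, q_hi, t_lo, t_hi, pad=k)
        if aln is not None:
            out.append(aln)
    # deterministic order: by query start, longest first
    out.sort(key=lambda a: (a.q_start, -(a.q_end - a.q_start)))
    return out


def merge_query_disjoint(alignments: list[LocalAlignment]) -> list[LocalAlignment]:
    """Greedily keep alignments that do not overlap on the query.

    Longest (most columns) first; used to merge multiple local alignments
    into one non-redundant set before summing matches/columns.
    """
    chosen: list[LocalAlignment] = []
    for aln in sorted(alignments, key=lambda a: (-a.columns, a.q_start)):
        if all(aln.q_end <= c.q_start or aln.q_start >= c.q_end for c in chosen):
            chosen.append(aln)
    chosen.sort(key=lambda a: a.q_start)
    return chosen
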