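"""Virus-host prediction from CRISPR spacers and nucleotide similarity.

Two independent lines of evidence, mirroring standard practice:

* CRISPR spacers found in host genomes are matched against viral contigs
  with zero mismatches by default -- an exact protospacer implies a past
  infection of that host lineage.
* Direct sequence similarity between a viral contig and a host genome,
  accepted only when the local alignment clears all of: bit score >= 50,
  E-value <= 1e-3, >= 70% identity, over >= 2,500 aligned bp.

The array finder is genome-based and requires exact repeat copies
(favouring precision over the read-based detectors it stands in for);
E-values use ungapped Karlin-Altschul statistics for the +1/-2
nucleotide scoring so thresholds stay auditable.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from ._align import local_alignments, revcomp

# ungapped Karlin-Altschul parameters for match +1 / mismatch -2
_KA_LAMBDA = 1.28
_KA_K = 0.46


@dataclass
class CrisprArray:
    """A CRISPR array: identical repeats alternating with spacers."""

    host: str
    repeat: str
    spacers: list[str]
    spacer_coords: list[tuple[int, int]]  # 0-based half-open host coordinates
    start: int = 0
    end: int = 0


@dataclass(frozen=True)
class SpacerMatch:
    spacer: str
    contig_id: str
    position: int
    strand: str
    mismatches: int


@dataclass
class HostLink:
    votu: str
    host: str
    evidence: str  # "crispr" | "similarity"
    detail: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# CRISPR array detection


def _common_prefix_len(seq: str, i: int, j: int, cap: int) -> int:
    n = 0
    limit = min(cap, len(seq) - j)
    while n < limit and seq[i + n] == seq[j + n]:
        n += 1
    return n


def find_crispr_arrays(
    genome: str,
    host: str = "",
    repeat_len_range: tuple[int, int] = (23, 47),
    spacer_len_range: tuple[int, int] = (26, 50),
    min_repeats: int = 3,
) -> list[CrisprArray]:
    """Deterministic left-to-right scan for runs of identical repeats.

    A candidate is seeded wherever a repeat-minimum-length word recurs at
    spacings compatible with one repeat plus one in-range spacer.  Every
    full repeat copy contains that word, so the run of its occurrences
    gives the repeat starts directly; the repeat length is the minimum
    common extension over all consecutive occurrence pairs (using only the
    first pair would absorb shared spacer prefixes into the repeat and
    break the run).  Arrays need >= ``min_repeats`` identical repeat copies.
    """
    rmin, rmax = repeat_len_range
    smin, smax = spacer_len_range
    k = rmin
    if len(genome) <= 2 * (rmin + smin):
        return []
    positions: dict[str, list[int]] = {}
    for i in range(len(genome) - k + 1):
        positions.setdefault(genome[i : i + k], []).append(i)

    candidates: list[tuple[list[int], int]] = []  # (repeat starts, repeat length)
    for kmer, occ in positions.items():
        if len(occ) < min_repeats:
            continue
        starts = [occ[0]]
        for nxt in occ[1:]:
            gap = nxt - starts[-1]
            if rmin + smin <= gap <= rmax + smax:
                starts.append(nxt)
            else:
                break
        if len(starts) < min_repeats:
            continue
        gaps = [b - a for a, b in zip(starts, starts[1:])]
        lce = min(
            _common_prefix_len(genome, a, b, cap=min(rmax, g))
            for a, b, g in zip(starts, starts[1:], gaps)
        )
        L = min(lce, rmax, min(gaps) - smin)
        if L < rmin or any(g - L > smax for g in gaps):
            continue
        candidates.append((starts, L))

    # the same array seeds several overlapping candidates (words offset into
    # the repeat, or flanking coincidences); keep maximal non-overlapping
    # ones, preferring more repeat copies, then the leftmost start
    candidates.sort(key=lambda c: (-len(c[0]), c[0][0]))
    arrays: list[CrisprArray] = []
    taken: list[tuple[int, int]] = []
    for starts, L in candidates:
        span = (starts[0], starts[-1] + L)
        if any(span[0] < e and span[1] > s for s, e in taken):
            continue
        taken.append(span)
        spacers, coords = [], []
        for a, b in zip(starts, starts[1:]):
            spacers.append(genome[a + L : b])
            coords.append((a + L, b))
        arrays.append(
            CrisprArray(
                host=host,
                repeat=genome[starts[0] : starts[0] + L],
                spacers=spacers,
                spacer_coords=coords,
                start=starts[0],
                end=starts[-1] + L,
            )
        )
    arrays.sort(key=lambda a: a.start)
    return arrays


# ---------------------------------------------------------------------------
# spacer matching


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def match_spacers(
    spacers: Mapping[str, str] | list[str],
    viral_contigs: Mapping[str, str],
    max_mismatch: int = 0,
) -> list[SpacerMatch]:
    """Every occurrence of every spacer on either strand, exhaustively.

    Occurrences with more than ``max_mismatch`` substitutions are not
    reported.  Spacers shorter than 20 bp trigger a low-specificity warning
    but are still processed.
    """
    if isinstance(spacers, Mapping):
        items = sorted(spacers.items())
    else:
        items = [(s, s) for s in spacers]
    if not items:
        raise ValueError("no spacers supplied")
    matches: list[SpacerMatch] = []
    encoded = {cid: _encode(seq) for cid, seq in viral_contigs.items()}
    for _, spacer in items:
        if len(spacer) < 20:
            warnings.warn(f"spacer {spacer[:12]}... is <20 bp: low matching specificity")
        for strand, probe in (("+", spacer), ("-", revcomp(spacer))):
            parr = _encode(probe)
            for cid in sorted(viral_contigs):
                carr = encoded[cid]
                if len(carr) < len(parr):
                    continue
                windows = np.lib.stride_tricks.sliding_window_view(carr, len(parr))
                mm = (windows != parr).sum(axis=1)
                for pos in np.nonzero(mm <= max_mismatch)[0]:
                    matches.append(
                        SpacerMatch(
                            spacer=spacer,
                            contig_id=cid,
                            position=int(pos),
                            strand=strand,
                            mismatches=int(mm[pos]),
                        )
                    )
    matches.sort(key=lambda m: (m.spacer, m.contig_id, m.position, m.strand))
    return matches


# ---------------------------------------------------------------------------
# similarity linkage


def bitscore(matches: int, columns: int) -> float:
    """Karlin-Altschul bit score of an ungapped-scored local alignment.

    Raw score is +1 per match, -2 per non-match column (the common
    nucleotide-search dialect); gaps are penalised like mismatches.
    """
    raw = matches - 2 * (columns - matches)
    return (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)


def evalue(bit: float, query_len: int, subject_len: int) -> float:
    return query_len * subject_len * 2.0 ** (-bit)


def similarity_link(
    viral_contigs: Mapping[str, str],
    host_genomes: Mapping[str, str],
    min_bitscore: float = 50.0,
    max_evalue: float = 1e-3,
    min_ani: float = 0.70,
    min_len: int = 2_500,
) -> list[HostLink]:
    """Nucleotide-similarity host links; all four thresholds must pass.

    One link per (vOTU, host) pair, carrying the best qualifying alignment's
    statistics.  Anchoring uses a short k-mer (11) so that alignments down
    to ~70% identity are still seeded.
    """
    links: list[HostLink] = []
    for vid in sorted(viral_contigs):
        vseq = viral_contigs[vid]
        for hid in sorted(host_genomes):
            hseq = host_genomes[hid]
            best = None
            for aln in local_alignments(vseq, hseq, k=11, min_anchors=2):
                if aln.columns < min_len:
                    continue
                ani = aln.identity
                if ani < min_ani:
                    continue
                bit = bitscore(aln.matches, aln.columns)
                if bit < min_bitscore:
                    continue
                ev = evalue(bit, len(vseq), len(hseq))
                if ev > max_evalue:
                    continue
                stats = {
                    "ani": ani,
                    "aligned_len": aln.columns,
                    "bitscore": bit,
                    "evalue": ev,
                    "v_start": aln.q_start,
                    "v_end": aln.q_end,
                    "h_start": aln.t_start,
                    "h_end": aln.t_end,
                }
                if best is None or stats["bitscore"] > best["bitscore"]:
                    best = stats
            if best is not None:
                links.append(HostLink(votu=vid, host=hid, evidence="similarity", detail=best))
    return links


def crispr_links(
    host_arrays: Mapping[str, list[CrisprArray]],
    viral_contigs: Mapping[str, str],
    contig_votu: Mapping[str, str] | None = None,
    max_mismatch: int = 0,
) -> list[HostLink]:
    """Host links from spacer matches, collapsed per (vOTU, host) pair."""
    seen: dict[tuple[str, str], HostLink] = {}
    for host in sorted(host_arrays):
        spacers = {
            f"{host}_a{ai}_s{si}": sp
            for ai, arr in enumerate(host_arrays[host])
            for si, sp in enumerate(arr.spacers)
        }
        if not spacers:
            continue
        for m in match_spacers(spacers, viral_contigs, max_mismatch=max_mismatch):
            votu = contig_votu[m.contig_id] if contig_votu else m.contig_id
            key = (votu, host)
            if key not in seen:
                seen[key] = HostLink(
                    votu=votu,
                    host=host,
                    evidence="crispr",
                    detail={"matches": []},
                )
            seen[key].detail["matches"].append(m)
    return [seen[k] for k in sorted(seen)]
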