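"""Contig dereplication into viral populations (vOTUs).

Viral populations are approximated species-level units: contigs sharing
>=95% average nucleotide identity (ANI) across >=80% of the (shorter)
contig length collapse into one vOTU, represented by the longest member.
Clustering is greedy longest-first, the standard dereplication scheme:
each contig joins the first existing representative it qualifies against,
otherwise it seeds a new population.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

from ._align import KmerIndex, LocalAlignment, local_alignments, merge_query_disjoint

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class AniResult:
    """Pairwise ANI between two sequences.

    ani               fraction of identical columns over all aligned columns
                      (N never counts as a match)
    aligned_fraction  aligned query span / length of the shorter sequence
    aligned_len       total alignment columns over the merged local alignments
    """

    ani: float
    aligned_fraction: float
    aligned_len: int


@dataclass
class VOTU:
    """A viral population: representative contig plus its members."""

    id: str
    representative: str
    members: set[str] = field(default_factory=set)
    length: int = 0


def _check_sequence(seq: str, name: str) -> None:
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{name}: invalid characters {sorted(bad)!r} (alphabet is A,C,G,T,N)")


def compute_ani(
    seq_a: str,
    seq_b: str,
    k: int = 13,
    _index: "KmerIndex | None" = None,
) -> AniResult:
    """Average nucleotide identity between two sequences.

    The shorter sequence is anchored against the longer one; local
    alignments are merged over non-overlapping query spans, and ANI is
    matches / aligned columns over the merged set.  The result is exactly
    symmetric because the pair is canonically ordered before alignment.

    ``_index`` optionally reuses a prebuilt KmerIndex of the *longer*
    sequence (an optimisation for repeated comparisons against one
    representative); it must have been built with the same ``k``.
    """
    _check_sequence(seq_a, "seq_a")
    _check_sequence(seq_b, "seq_b")
    # canonical order: shorter (ties: lexicographically smaller) is the query
    if (len(seq_a), seq_a) <= (len(seq_b), seq_b):
        query, target = seq_a, seq_b
    else:
        query, target = seq_b, seq_a
        _index = None  # index was built for seq_b as target; orientation flipped
    alns = local_alignments(query, target, k=k, index=_index)
    merged = merge_query_disjoint(alns)
    if not merged:
        return AniResult(ani=0.0, aligned_fraction=0.0, aligned_len=0)
    matches = sum(a.matches for a in merged)
    columns = sum(a.columns for a in merged)
    span = sum(a.q_end - a.q_start for a in merged)
    return AniResult(
        ani=matches / columns,
        aligned_fraction=min(1.0, span / len(query)),
        aligned_len=columns,
    )


def cluster_contigs(
    contigs: Mapping[str, str],
    min_ani: float = 0.95,
    min_cov: float = 0.80,
    min_length: int = 0,
    k: int = 13,
) -> list[VOTU]:
    """Greedy longest-first clustering of contigs into vOTUs.

    Contigs are sorted by length descending (ties broken lexicographically
    by id), each seeding a new cluster unless it reaches ``min_ani`` over
    ``min_cov`` of the shorter length against an existing representative.
    ``min_length`` optionally drops short contigs up front (the original
    study used a 10 kb floor; off by default).

    Deterministic given the input; duplicate ids raise ValueError.
    """
    ids = list(contigs)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in input")
    if min_length:
        dropped = [i for i in ids if len(contigs[i]) < min_length]
        if dropped:
            warnings.warn(f"{len(dropped)} contigs below {min_length} bp dropped")
        ids = [i for i in ids if len(contigs[i]) >= min_length]
    order = sorted(ids, key=lambda i: (-len(contigs[i]), i))

    votus: list[VOTU] = []
    indexes: list[KmerIndex] = []
    for cid in order:
        seq = contigs[cid]
        placed = False
        for votu, idx in zip(votus, indexes):
            res = compute_ani(seq, contigs[votu.representative], k=k, _index=idx)
            if res.ani >= min_ani and res.aligned_fraction >= min_cov:
                votu.members.add(cid)
                placed = True
                break
        if not placed:
            votus.append(
                VOTU(
                    id=f"vOTU_{len(votus) + 1:04d}",
                    representative=cid,
                    members={cid},
                    length=len(seq),
                )
            )
            indexes.append(KmerIndex(seq, k))
    return votus


def membership_table(votus: list[VOTU]) -> list[tuple[str, str, bool]]:
    """(contig_id, votu_id, is_representative) rows, sorted for stable output."""
    rows = []
    for v in votus:
        for m in sorted(v.members):
            rows.append((m, v.id, m == v.representative))
    rows.sort()
    return rows
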