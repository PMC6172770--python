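"""Habitat-structured synthetic viral communities with full ground truth.

Emulates the sampling design of a permafrost-thaw virome survey: three
habitats along a thaw gradient (palsa / bog / fen) hold partially
overlapping pools of viral populations; abundances follow a log-normal
within each habitat; the viral fraction of each library grows along the
gradient by a configurable fold factor (bog 3x, fen 12x relative to palsa
by default); reads carry uniform point errors; host genomes carry CRISPR
arrays whose spacers are exact protospacers sampled from viral genomes;
and genomes receive planted protein-family content that induces a known
viral-cluster structure downstream.

Genome sequences are i.i.d. uniform nucleotides except planted
protospacers and shared segments, which maximises contrast for ANI-based
operations.  Every read, spacer, and protein traces to exactly one ground
truth record.  All randomness flows from one master seed, with one
decoupled pseudo-random stream per operation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from ._align import revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STREAMS = {"community": 1, "reads": 2, "hosts": 3, "genes": 4, "contaminants": 5}


class ConfigError(ValueError):
    """Invalid simulation or pipeline configuration."""


def _rng(seed: int, operation: str) -> np.random.Generator:
    """One pseudo-random stream per operation, derived from the master seed."""
    return np.random.default_rng([seed, _STREAMS[operation]])


def random_sequence(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, length)].tobytes().decode()


def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitute each position with probability ``rate`` (always to a different base)."""
    codes = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    idx = {b: i for i, b in enumerate(_BASES)}
    num = np.array([idx.get(b, 0) for b in codes], dtype=np.uint8)
    mask = rng.random(len(seq)) < rate
    shift = rng.integers(1, 4, len(seq)).astype(np.uint8)
    num = np.where(mask, (num + shift) % 4, num)
    return _BASES[num].tobytes().decode()


# ---------------------------------------------------------------------------
# community


@dataclass
class CommunityConfig:
    """Shape of the synthetic habitat-structured community.

    Defaults emulate the study system: three thaw-gradient habitats with
    partially overlapping vOTU pools (no palsa-fen sharing), genome sizes in
    the 12-18 kb range, moderate log-normal abundance spread, and a 1/3/12
    habitat fold gradient in viral library fraction.
    """

    habitats: tuple[str, ...] = ("palsa", "bog", "fen")
    votus_per_habitat: int = 8
    overlaps: dict[tuple[str, str], int] = field(
        default_factory=lambda: {("palsa", "bog"): 2, ("bog", "fen"): 2, ("palsa", "fen"): 0}
    )
    genome_length_range: tuple[int, int] = (12_000, 18_000)
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 0.5
    habitat_fold_gradient: dict[str, float] = field(
        default_factory=lambda: {"palsa": 1.0, "bog": 3.0, "fen": 12.0}
    )
    contigs_per_votu: tuple[int, int] = (2, 3)
    variant_divergence: float = 0.02
    variant_min_fraction: float = 0.85
    seed: int = 0

    def validate(self) -> None:
        if len(self.habitats) < 1:
            raise ConfigError("at least one habitat required")
        for (a, b), n in self.overlaps.items():
            if a not in self.habitats or b not in self.habitats:
                raise ConfigError(f"overlap names unknown habitat: ({a}, {b})")
            if n < 0 or n > self.votus_per_habitat:
                raise ConfigError(
                    f"overlap({a},{b})={n} exceeds the smaller pool size "
                    f"({self.votus_per_habitat})"
                )
        for h in self.habitats:
            shared = sum(n for pair, n in self.overlaps.items() if h in pair)
            if shared > self.votus_per_habitat:
                raise ConfigError(
                    f"habitat {h!r}: requested overlaps total {shared} > pool size "
                    f"{self.votus_per_habitat}"
                )
        for h, f in self.habitat_fold_gradient.items():
            if f <= 0:
                raise ConfigError(f"fold factor for {h!r} must be > 0 (got {f})")
        lo, hi = self.genome_length_range
        if not (0 < lo <= hi):
            raise ConfigError("invalid genome_length_range")


@dataclass
class TruthHostLink:
    host: str
    virus: str
    evidence: str  # "crispr" | "similarity"
    spacer: str = ""
    strand: str = "+"


@dataclass
class GroundTruth:
    """Complete provenance of a synthetic scenario."""

    votu_memberships: dict[str, str] = field(default_factory=dict)  # contig -> genome
    abundance_table: pd.DataFrame | None = None  # habitat x genome, rows sum to 1
    presence: pd.DataFrame | None = None  # habitat x genome booleans
    host_links: list[TruthHostLink] = field(default_factory=list)
    pc_assignments: dict[str, str] = field(default_factory=dict)  # protein -> family
    vc_assignments: dict[str, str] = field(default_factory=dict)  # genome -> planted VC
    contaminants: set[str] = field(default_factory=set)


@dataclass
class SyntheticCommunity:
    genomes: dict[str, str]  # genome (vOTU representative) sequences
    contigs: dict[str, str]  # member contigs, keyed by contig id
    habitat_pools: dict[str, list[str]]  # habitat -> genome ids present


def simulate_community(config: CommunityConfig) -> tuple[SyntheticCommunity, GroundTruth]:
    """Realise habitat pools, per-habitat abundances, and member contigs."""
    config.validate()
    rng = _rng(config.seed, "community")
    counter = 0

    def new_genome_id() -> str:
        nonlocal counter
        counter += 1
        return f"votu{counter:04d}"

    pools: dict[str, list[str]] = {h: [] for h in config.habitats}
    genomes: dict[str, str] = {}
    lo, hi = config.genome_length_range
    # shared genomes first (pairwise overlaps), in a deterministic pair order
    for (a, b), n in sorted(config.overlaps.items()):
        for _ in range(n):
            g = new_genome_id()
            genomes[g] = random_sequence(rng, int(rng.integers(lo, hi + 1)))
            pools[a].append(g)
            pools[b].append(g)
    # habitat-unique genomes fill each pool
    for h in config.habitats:
        while len(pools[h]) < config.votus_per_habitat:
            g = new_genome_id()
            genomes[g] = random_sequence(rng, int(rng.integers(lo, hi + 1)))
            pools[h].append(g)

    all_ids = sorted(genomes)
    presence = pd.DataFrame(False, index=list(config.habitats), columns=all_ids)
    abundance = pd.DataFrame(0.0, index=list(config.habitats), columns=all_ids)
    for h in config.habitats:
        present = sorted(pools[h])
        presence.loc[h, present] = True
        draws = rng.lognormal(config.lognormal_mu, config.lognormal_sigma, len(present))
        abundance.loc[h, present] = draws / draws.sum()

    truth = GroundTruth(abundance_table=abundance, presence=presence)

    contigs: dict[str, str] = {}
    c_lo, c_hi = config.contigs_per_votu
    for g in all_ids:
        seq = genomes[g]
        contigs[f"{g}.c1"] = seq
        truth.votu_memberships[f"{g}.c1"] = g
        for j in range(2, int(rng.integers(c_lo, c_hi + 1)) + 1):
            frac = rng.uniform(config.variant_min_fraction, 1.0)
            length = int(len(seq) * frac)
            start = int(rng.integers(0, len(seq) - length + 1))
            cid = f"{g}.c{j}"
            contigs[cid] = mutate(seq[start : start + length], config.variant_divergence, rng)
            truth.votu_memberships[cid] = g

    return SyntheticCommunity(genomes=genomes, contigs=contigs, habitat_pools=pools), truth


def plant_contaminants(
    community: SyntheticCommunity,
    truth: GroundTruth,
    n_contaminants: int = 1,
    n_references: int = 2,
    length: int = 12_000,
    divergence: float = 0.02,
    seed: int = 0,
) -> dict[str, str]:
    """Add lab-contaminant reference genomes and plant near-copies among contigs.

    Returns the reference set; planted contigs are recorded in
    ``truth.contaminants`` so the screening stage can be scored.
    """
    rng = _rng(seed, "contaminants")
    refs = {f"labphage{i + 1}": random_sequence(rng, length) for i in range(n_references)}
    ref_ids = sorted(refs)
    for i in range(n_contaminants):
        src = refs[ref_ids[i % len(ref_ids)]]
        cid = f"contam{i + 1}.c1"
        community.contigs[cid] = mutate(src, divergence, rng)
        truth.contaminants.add(cid)
    return refs


# ---------------------------------------------------------------------------
# reads


def simulate_reads(
    genomes: Mapping[str, str],
    abundances: Mapping[str, float],
    n_reads: int,
    read_len: int = 100,
    err_rate: float = 0.01,
    seed: int = 0,
    rc_prob: float = 0.5,
    read_prefix: str = "r",
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Draw reads from genomes with probability proportional to abundance x length.

    Start positions are uniform; substitutions occur independently at
    ``err_rate``; orientation is reverse-complemented with probability
    ``rc_prob``.  Returns the reads and a per-read origin table
    (genome, start, strand).
    """
    ids = sorted(genomes)
    if not ids:
        raise ValueError("no genomes supplied")
    abund = np.array([abundances[g] for g in ids], dtype=float)
    if abs(abund.sum() - 1.0) > 1e-6:
        raise ValueError(f"abundances must sum to 1 (got {abund.sum():.6f})")
    if not 0 <= err_rate < 0.25:
        raise ValueError(f"err_rate must be in [0, 0.25) (got {err_rate})")
    shortest = min(len(genomes[g]) for g in ids)
    if read_len > shortest:
        raise ValueError(f"read_len {read_len} exceeds shortest genome ({shortest} bp)")

    rng = _rng(seed, "reads")
    lengths = np.array([len(genomes[g]) for g in ids], dtype=float)
    p = abund * lengths
    p /= p.sum()
    counts = rng.multinomial(n_reads, p)

    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[b] = i

    reads: list[tuple[str, str]] = []
    origin_rows = []
    serial = 0
    for g, cnt in zip(ids, counts):
        if cnt == 0:
            continue
        codes = lut[np.frombuffer(genomes[g].encode(), dtype=np.uint8)]
        starts = rng.integers(0, len(codes) - read_len + 1, cnt)
        mat = codes[starts[:, None] + np.arange(read_len)]
        if err_rate > 0:
            mask = rng.random(mat.shape) < err_rate
            shift = rng.integers(1, 4, mat.shape).astype(np.uint8)
            mat = np.where(mask, (mat + shift) % 4, mat)
        rc = rng.random(cnt) < rc_prob
        mat[rc] = (3 - mat[rc])[:, ::-1]
        seqs = _BASES[mat]
        for row, start, is_rc in zip(seqs, starts, rc):
            rid = f"{read_prefix}{serial:07d}"
            serial += 1
            reads.append((rid, row.tobytes().decode()))
            origin_rows.append((rid, g, int(start), "-" if is_rc else "+"))
    origin = pd.DataFrame(origin_rows, columns=["read_id", "genome", "start", "strand"])
    return reads, origin.set_index("read_id")


# ---------------------------------------------------------------------------
# hosts with CRISPR arrays


def simulate_hosts_with_crispr(
    host_count: int,
    viral_genomes: Mapping[str, str],
    spacers_per_array: int = 5,
    repeat_len: int = 32,
    spacer_len: int = 32,
    seed: int = 0,
    *,
    host_length: int = 40_000,
    n_similarity_hosts: int = 1,
    n_free_hosts: int = 1,
    similarity_segment_len: int = 3_000,
) -> tuple[dict[str, str], list[TruthHostLink]]:
    """Host genomes carrying CRISPR arrays whose spacers sample viral genomes.

    Hosts are partitioned deterministically: the first ``n_similarity_hosts``
    carry a planted shared viral segment (similarity-linkable), the last
    ``n_free_hosts`` carry no viral trace at all, and the remainder carry one
    CRISPR array of ``spacers_per_array`` spacers (repeat-spacer-...-repeat,
    so spacers_per_array + 1 identical repeat copies).  Every protospacer is
    an exact substring of its source viral genome; the stored strand is
    recorded in the truth.
    """
    vids = sorted(viral_genomes)
    if not vids:
        raise ValueError("no viral genomes supplied")
    shortest = min(len(viral_genomes[v]) for v in vids)
    if spacer_len > shortest:
        raise ValueError(f"spacer_len {spacer_len} exceeds shortest viral genome")
    if n_similarity_hosts and similarity_segment_len > shortest:
        raise ValueError("similarity_segment_len exceeds shortest viral genome")
    if n_similarity_hosts + n_free_hosts > host_count:
        raise ConfigError("host_count too small for the requested link layout")

    rng = _rng(seed, "hosts")
    hosts: dict[str, str] = {}
    links: list[TruthHostLink] = []
    vcursor = 0
    for i in range(host_count):
        hid = f"host{i + 1:02d}"
        base = random_sequence(rng, host_length)
        if i < n_similarity_hosts:
            virus = vids[vcursor % len(vids)]
            vcursor += 1
            vseq = viral_genomes[virus]
            pos = int(rng.integers(0, len(vseq) - similarity_segment_len + 1))
            segment = vseq[pos : pos + similarity_segment_len]
            at = int(rng.integers(0, len(base)))
            base = base[:at] + segment + base[at:]
            links.append(TruthHostLink(host=hid, virus=virus, evidence="similarity"))
        elif i < host_count - n_free_hosts:
            repeat = random_sequence(rng, repeat_len)
            parts = [repeat]
            for _ in range(spacers_per_array):
                virus = vids[vcursor % len(vids)]
                vcursor += 1
                vseq = viral_genomes[virus]
                pos = int(rng.integers(0, len(vseq) - spacer_len + 1))
                proto = vseq[pos : pos + spacer_len]
                if rng.random() < 0.5:
                    stored, strand = revcomp(proto), "-"
                else:
                    stored, strand = proto, "+"
                parts.append(stored)
                parts.append(repeat)
                links.append(
                    TruthHostLink(
                        host=hid, virus=virus, evidence="crispr", spacer=stored, strand=strand
                    )
                )
            array = "".join(parts)
            at = int(rng.integers(0, len(base)))
            base = base[:at] + array + base[at:]
        hosts[hid] = base
    return hosts, links


# ---------------------------------------------------------------------------
# gene content


@dataclass
class GeneContentPlan:
    """Planned viral-cluster structure expressed as shared protein families.

    clusters        genome-id groups that should emerge as viral clusters
    intra_shared    families shared by every genome within a cluster (the core)
    inter_shared    families bridging consecutive cluster pairs (one carrier
                    genome per side); must stay below ``intra_shared``
    """

    clusters: list[list[str]]
    intra_shared: int = 10
    inter_shared: int = 0

    def validate(self) -> None:
        if self.inter_shared >= self.intra_shared:
            raise ConfigError(
                f"inter-cluster sharing ({self.inter_shared}) must be below "
                f"intra-cluster sharing ({self.intra_shared})"
            )
        seen: set[str] = set()
        for grp in self.clusters:
            for g in grp:
                if g in seen:
                    raise ConfigError(f"genome {g!r} appears in two planned clusters")
                seen.add(g)


def default_gene_plan(genome_ids: Sequence[str], n_clusters: int = 4, **kw) -> GeneContentPlan:
    """Partition genomes into contiguous, near-equal planned clusters."""
    ids = sorted(genome_ids)
    chunks: list[list[str]] = [[] for _ in range(n_clusters)]
    for i, g in enumerate(ids):
        chunks[i * n_clusters // len(ids)].append(g)
    return GeneContentPlan(clusters=[c for c in chunks if c], **kw)


def simulate_gene_content(
    vc_plan: GeneContentPlan,
    families_per_genome: int = 15,
    seed: int = 0,
) -> tuple[dict[str, list[str]], pd.DataFrame, dict[str, str], GroundTruth]:
    """Per-genome protein-family content plus an all-vs-all similarity edge list.

    Genomes in the same planned cluster share their cluster core families;
    remaining slots are filled with genome-unique families.  The emitted edge
    table connects every protein pair within a family (BLASTp-tabular-like
    columns: query, subject, bitscore, evalue).

    Returns (families per genome, edge table, protein->genome map, truth)
    where truth carries pc_assignments and vc_assignments.
    """
    vc_plan.validate()
    rng = _rng(seed, "genes")
    truth = GroundTruth()
    fam_counter = 0

    def new_family() -> str:
        nonlocal fam_counter
        fam_counter += 1
        return f"fam{fam_counter:04d}"

    genome_families: dict[str, list[str]] = {}
    for ci, grp in enumerate(vc_plan.clusters):
        core = [new_family() for _ in range(vc_plan.intra_shared)]
        for g in grp:
            if len(grp) > 1:
                genome_families[g] = list(core)
            else:
                genome_families[g] = []  # planned singleton shares nothing
            truth.vc_assignments[g] = f"plantedVC{ci + 1}"
    for ci in range(len(vc_plan.clusters) - 1):
        a, b = vc_plan.clusters[ci], vc_plan.clusters[ci + 1]
        for _ in range(vc_plan.inter_shared):
            fam = new_family()
            genome_families[a[0]].append(fam)
            genome_families[b[0]].append(fam)
    for g in sorted(genome_families):
        while len(genome_families[g]) < families_per_genome:
            genome_families[g].append(new_family())
        if len(genome_families[g]) > families_per_genome:
            raise ConfigError(
                f"genome {g!r}: planned shared families exceed families_per_genome"
            )

    protein_genome: dict[str, str] = {}
    family_members: dict[str, list[str]] = {}
    for g in sorted(genome_families):
        for k, fam in enumerate(genome_families[g]):
            pid = f"{g}|p{k + 1:03d}"
            protein_genome[pid] = g
            truth.pc_assignments[pid] = fam
            family_members.setdefault(fam, []).append(pid)

    rows = []
    for fam in sorted(family_members):
        members = family_members[fam]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                bit = float(rng.uniform(60, 200))
                ev = float(10 ** rng.uniform(-30, -10))
                rows.append((members[i], members[j], bit, ev))
                rows.append((members[j], members[i], bit, ev))
    edges = pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])
    return genome_families, edges, protein_genome, truth
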