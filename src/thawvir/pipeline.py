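"""Pipeline orchestration: configuration, stages, and provenance.

Stages run in a fixed order -- simulate, screen, dereplicate, quantify,
network, hostlink, ecology -- each reading and writing plain-text files
in a run directory, with a JSON manifest recording parameters, seeds and
output checksums.  All stage defaults are the study thresholds
(0.95/0.80 dereplication, 0.90/0.75 detection, 50 bit / 1e-4 protein
clustering, edge score >= 1, inflation grid 1.0-5.0 step 0.2, host
linkage 50 bit / 1e-3 / 70% / 2,500 bp).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import AbundanceMatrix, detect_and_quantify, filter_alignments, total_sum_scale
from .dereplicate import cluster_contigs, membership_table
from .ecology import (
    bray_curtis,
    codon_usage_profile,
    collectors_curve,
    diversity,
    habitat_fold_factors,
    habitat_sharing,
    pcoa,
    screen_contaminants,
)
from .hostlink import crispr_links, find_crispr_arrays, similarity_link
from .io import read_fasta, write_alignments_tsv, write_fasta, write_tsv_matrix
from .mapping import ReadMapper
from .network import DEFAULT_INFLATION_GRID, assign_viral_clusters, build_protein_clusters
from .synthio import (
    CommunityConfig,
    ConfigError,
    GroundTruth,
    SyntheticCommunity,
    default_gene_plan,
    plant_contaminants,
    simulate_community,
    simulate_gene_content,
    simulate_hosts_with_crispr,
    simulate_reads,
)

log = logging.getLogger("thawvir")

STAGES = ("simulate", "screen", "dereplicate", "quantify", "network", "hostlink", "ecology")


@dataclass
class ReadSimConfig:
    reads_per_habitat: dict[str, int] = field(
        default_factory=lambda: {"palsa": 100_000, "bog": 60_000, "fen": 25_000}
    )
    replicates: int = 2
    read_len: int = 100
    err_rate: float = 0.01
    viral_fraction_base: float = 0.08


@dataclass
class HostSimConfig:
    host_count: int = 6
    spacers_per_array: int = 5
    repeat_len: int = 32
    spacer_len: int = 32
    host_length: int = 40_000
    n_similarity_hosts: int = 1
    n_free_hosts: int = 1
    similarity_segment_len: int = 3_000


@dataclass
class GeneContentConfig:
    n_clusters: int = 4
    families_per_genome: int = 15
    intra_shared: int = 10
    inter_shared: int = 0


@dataclass
class ScreenConfig:
    n_contaminants: int = 1
    n_references: int = 2
    min_ani: float = 0.95


@dataclass
class DereplicateConfig:
    min_ani: float = 0.95
    min_cov: float = 0.80
    min_length: int = 0  # the original study used a 10 kb floor; optional here


@dataclass
class QuantifyConfig:
    min_read_ani: float = 0.90
    min_breadth: float = 0.75


@dataclass
class NetworkConfig:
    min_bitscore: float = 50.0
    max_evalue: float = 1e-4
    pc_inflation: float = 2.0
    score_threshold: float = 1.0
    inflation_grid: tuple[float, ...] = DEFAULT_INFLATION_GRID


@dataclass
class HostlinkConfig:
    max_mismatch: int = 0
    min_bitscore: float = 50.0
    max_evalue: float = 1e-3
    min_ani: float = 0.70
    min_len: int = 2_500
    repeat_len_range: tuple[int, int] = (23, 47)
    spacer_len_range: tuple[int, int] = (26, 50)
    min_repeats: int = 3


@dataclass
class EcologyConfig:
    n_randomizations: int = 50
    reference_habitat: str = "palsa"


@dataclass
class PipelineConfig:
    community: CommunityConfig = field(default_factory=CommunityConfig)
    reads: ReadSimConfig = field(default_factory=ReadSimConfig)
    hosts: HostSimConfig = field(default_factory=HostSimConfig)
    genes: GeneContentConfig = field(default_factory=GeneContentConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    dereplicate: DereplicateConfig = field(default_factory=DereplicateConfig)
    quantify: QuantifyConfig = field(default_factory=QuantifyConfig)
    network: NetworkConfig = field(default_factory=NetworkConfig)
    hostlink: HostlinkConfig = field(default_factory=HostlinkConfig)
    ecology: EcologyConfig = field(default_factory=EcologyConfig)
    seed: int = 0

    def validate(self) -> None:
        self.community.seed = self.seed
        self.community.validate()
        for name, frac in [
            ("quantify.min_read_ani", self.quantify.min_read_ani),
            ("quantify.min_breadth", self.quantify.min_breadth),
            ("dereplicate.min_ani", self.dereplicate.min_ani),
            ("dereplicate.min_cov", self.dereplicate.min_cov),
            ("hostlink.min_ani", self.hostlink.min_ani),
            ("screen.min_ani", self.screen.min_ani),
        ]:
            if not 0 < frac <= 1:
                raise ConfigError(f"{name} must be in (0, 1] (got {frac})")
        if not 0 <= self.reads.err_rate < 0.25:
            raise ConfigError("reads.err_rate must be in [0, 0.25)")
        for h in self.community.habitats:
            if h not in self.reads.reads_per_habitat:
                raise ConfigError(f"reads.reads_per_habitat missing habitat {h!r}")
            vf = self.reads.viral_fraction_base * self.community.habitat_fold_gradient.get(h, 1.0)
            if vf > 0.98:
                raise ConfigError(
                    f"viral fraction for habitat {h!r} is {vf:.2f} > 0.98; lower "
                    "reads.viral_fraction_base or the fold factor"
                )
        if self.ecology.reference_habitat not in self.community.habitats:
            raise ConfigError("ecology.reference_habitat is not a community habitat")

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["community"]["overlaps"] = {
            f"{a},{b}": n for (a, b), n in self.community.overlaps.items()
        }
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        data = dict(data)
        kwargs: dict[str, Any] = {}
        blocks = {
            "community": CommunityConfig,
            "reads": ReadSimConfig,
            "hosts": HostSimConfig,
            "genes": GeneContentConfig,
            "screen": ScreenConfig,
            "dereplicate": DereplicateConfig,
            "quantify": QuantifyConfig,
            "network": NetworkConfig,
            "hostlink": HostlinkConfig,
            "ecology": EcologyConfig,
        }
        for key, klass in blocks.items():
            if key in data:
                block = dict(data.pop(key))
                if key == "community" and "overlaps" in block:
                    block["overlaps"] = {
                        tuple(k.split(",")): v for k, v in block["overlaps"].items()
                    }
                if key == "community" and "habitats" in block:
                    block["habitats"] = tuple(block["habitats"])
                known = {f.name for f in dataclasses.fields(klass)}
                unknown = set(block) - known
                if unknown:
                    raise ConfigError(f"unknown keys in {key!r} block: {sorted(unknown)}")
                kwargs[key] = klass(**block)
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ConfigError(f"unknown top-level config keys: {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def _sample_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence([master, 1000 + index]).generate_state(1)[0] % 2**31)


@dataclass
class PipelineResult:
    config: PipelineConfig
    outdir: Path
    community: SyntheticCommunity
    truth: GroundTruth
    contaminant_refs: dict[str, str]
    flagged: list[str]
    votus: list
    membership: dict[str, str]  # contig -> recovered vOTU id
    representatives: dict[str, str]  # vOTU id -> sequence
    sample_habitats: dict[str, str]
    sample_total_bp: dict[str, int]
    abundance: AbundanceMatrix
    scaled: pd.DataFrame
    pcs: list
    profiles: list
    vc_assignment: Any
    crispr_arrays: dict[str, list]
    host_links: list
    ecology: dict[str, Any]


@dataclass
class SimulationBundle:
    """Everything stage_simulate produces, kept in memory for downstream stages."""

    community: SyntheticCommunity
    truth: GroundTruth
    refs: dict[str, str]
    hosts: dict[str, str]
    protein_edges: pd.DataFrame
    protein_genome: dict[str, str]
    sample_reads: dict[str, list[tuple[str, str]]]
    sample_habitats: dict[str, str]
    sample_total_bp: dict[str, int]


def simulate_scenario(config: PipelineConfig, outdir: str | Path) -> SimulationBundle:
    """Generate the full synthetic scenario and write it to a run directory."""
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "truth").mkdir(exist_ok=True)
    (outdir / "reads").mkdir(exist_ok=True)
    log.info("stage simulate: community, reads, hosts, gene content")
    community, truth = simulate_community(config.community)
    refs = plant_contaminants(
        community,
        truth,
        n_contaminants=config.screen.n_contaminants,
        n_references=config.screen.n_references,
        seed=config.seed,
    )
    hosts, truth_links = simulate_hosts_with_crispr(
        config.hosts.host_count,
        community.genomes,
        spacers_per_array=config.hosts.spacers_per_array,
        repeat_len=config.hosts.repeat_len,
        spacer_len=config.hosts.spacer_len,
        seed=config.seed,
        host_length=config.hosts.host_length,
        n_similarity_hosts=config.hosts.n_similarity_hosts,
        n_free_hosts=config.hosts.n_free_hosts,
        similarity_segment_len=config.hosts.similarity_segment_len,
    )
    truth.host_links = truth_links
    plan = default_gene_plan(
        community.genomes,
        n_clusters=config.genes.n_clusters,
        intra_shared=config.genes.intra_shared,
        inter_shared=config.genes.inter_shared,
    )
    _, protein_edges, protein_genome, gene_truth = simulate_gene_content(
        plan, families_per_genome=config.genes.families_per_genome, seed=config.seed
    )
    truth.pc_assignments = gene_truth.pc_assignments
    truth.vc_assignments = gene_truth.vc_assignments

    write_fasta(community.genomes, outdir / "votu_genomes.fasta")
    write_fasta(community.contigs, outdir / "contigs.fasta")
    write_fasta(refs, outdir / "contaminant_refs.fasta")
    write_fasta(hosts, outdir / "hosts.fasta")
    protein_edges.to_csv(outdir / "protein_edges.tsv", sep="\t", index=False)
    pd.Series(protein_genome, name="genome").rename_axis("protein").to_csv(
        outdir / "protein_genomes.tsv", sep="\t"
    )
    write_tsv_matrix(truth.abundance_table, outdir / "truth" / "abundance.tsv")
    write_tsv_matrix(truth.presence.astype(int), outdir / "truth" / "presence.tsv")
    pd.Series(truth.votu_memberships, name="votu").rename_axis("contig").to_csv(
        outdir / "truth" / "memberships.tsv", sep="\t"
    )
    pd.DataFrame(
        [(l.host, l.virus, l.evidence, l.spacer, l.strand) for l in truth.host_links],
        columns=["host", "virus", "evidence", "spacer", "strand"],
    ).to_csv(outdir / "truth" / "host_links.tsv", sep="\t", index=False)

    sample_habitats: dict[str, str] = {}
    sample_total_bp: dict[str, int] = {}
    sample_reads: dict[str, list[tuple[str, str]]] = {}
    n_hosts = len(hosts)
    idx = 0
    for h in config.community.habitats:
        vf = config.reads.viral_fraction_base * config.community.habitat_fold_gradient[h]
        n_reads = config.reads.reads_per_habitat[h]
        pool_abund = truth.abundance_table.loc[h]
        for rep in range(1, config.reads.replicates + 1):
            sid = f"{h}_{rep}"
            # reads are drawn proportional to abundance x length, so to give the
            # viral community a bp share of vf the per-genome abundance is the
            # bp share divided by the genome length (a particle density)
            abund = {
                g: vf * float(a) / len(community.genomes[g])
                for g, a in pool_abund.items()
                if a > 0
            }
            abund.update({hid: (1 - vf) / (n_hosts * len(hosts[hid])) for hid in hosts})
            z = sum(abund.values())
            abund = {k: v / z for k, v in abund.items()}
            pool = {g: community.genomes[g] for g in pool_abund.index[pool_abund > 0]}
            pool.update(hosts)
            reads, _ = simulate_reads(
                pool,
                abund,
                n_reads=n_reads,
                read_len=config.reads.read_len,
                err_rate=config.reads.err_rate,
                seed=_sample_seed(config.seed, idx),
                read_prefix=f"{sid}.r",
            )
            sample_reads[sid] = reads
            sample_habitats[sid] = h
            sample_total_bp[sid] = n_reads * config.reads.read_len
            write_fasta(dict(reads), outdir / "reads" / f"{sid}.fasta")
            idx += 1
    pd.DataFrame(
        {
            "habitat": pd.Series(sample_habitats),
            "total_bp": pd.Series(sample_total_bp),
        }
    ).rename_axis("sample").to_csv(outdir / "sample_table.tsv", sep="\t")
    return SimulationBundle(
        community=community,
        truth=truth,
        refs=refs,
        hosts=hosts,
        protein_edges=protein_edges,
        protein_genome=protein_genome,
        sample_reads=sample_reads,
        sample_habitats=sample_habitats,
        sample_total_bp=sample_total_bp,
    )


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> PipelineResult:
    """Execute all stages on a synthetic scenario and write a provenance manifest."""
    config.validate()
    outdir = Path(outdir)
    sim = simulate_scenario(config, outdir)
    community, truth = sim.community, sim.truth
    refs, hosts = sim.refs, sim.hosts
    protein_edges, protein_genome = sim.protein_edges, sim.protein_genome
    sample_reads = sim.sample_reads
    sample_habitats, sample_total_bp = sim.sample_habitats, sim.sample_total_bp

    # -- screen ---------------------------------------------------------------
    flagged = screen_contaminants(community.contigs, refs, min_ani=config.screen.min_ani)
    log.info("stage screen: %d of %d contigs flagged", len(flagged), len(community.contigs))
    screened = {c: s for c, s in community.contigs.items() if c not in flagged}
    pd.Series(sorted(flagged), name="contig").to_csv(outdir / "flagged_contigs.tsv", sep="\t", index=False)
    write_fasta(screened, outdir / "contigs_screened.fasta")

    # -- dereplicate ----------------------------------------------------------
    votus = cluster_contigs(
        screened,
        min_ani=config.dereplicate.min_ani,
        min_cov=config.dereplicate.min_cov,
        min_length=config.dereplicate.min_length,
    )
    log.info("stage dereplicate: %d contigs -> %d vOTUs", len(screened), len(votus))
    membership = {c: v for c, v, _ in membership_table(votus)}
    representatives = {v.id: screened[v.representative] for v in votus}
    pd.DataFrame(membership_table(votus), columns=["contig", "votu", "is_representative"]).to_csv(
        outdir / "votus.tsv", sep="\t", index=False
    )
    write_fasta(representatives, outdir / "representatives.fasta")

    # -- quantify -------------------------------------------------------------
    mapper = ReadMapper(representatives)
    rows = {}
    lengths = {v: len(s) for v, s in representatives.items()}
    for sid in sample_habitats:
        raw = mapper.map_reads(sample_reads[sid])
        kept = filter_alignments(raw, min_read_ani=config.quantify.min_read_ani)
        log.info(
            "stage quantify [%s]: %d reads mapped, %d pass %.0f%% identity",
            sid, len(raw), len(kept), config.quantify.min_read_ani * 100,
        )
        write_alignments_tsv(kept, outdir / "reads" / f"{sid}.alignments.tsv")
        rows[sid] = detect_and_quantify(
            kept, lengths, total_bp=sample_total_bp[sid], min_breadth=config.quantify.min_breadth
        )
    matrix = AbundanceMatrix.from_samples(rows)
    scaled = total_sum_scale(matrix.values)
    write_tsv_matrix(matrix.values, outdir / "abundance.tsv")
    write_tsv_matrix(matrix.breadth, outdir / "breadth.tsv")
    write_tsv_matrix(matrix.detected.astype(int), outdir / "detected.tsv")
    write_tsv_matrix(scaled, outdir / "abundance_scaled.tsv")

    # -- network --------------------------------------------------------------
    pcs, profiles = build_protein_clusters(
        protein_edges,
        protein_genome,
        min_bitscore=config.network.min_bitscore,
        max_evalue=config.network.max_evalue,
        inflation=config.network.pc_inflation,
    )
    vc = assign_viral_clusters(
        profiles,
        inflation_grid=config.network.inflation_grid,
        score_threshold=config.network.score_threshold,
    )
    log.info(
        "stage network: %d PCs, %d edges, optimum inflation %.1f",
        len(pcs), len(vc.edges), vc.inflation,
    )
    pd.DataFrame(
        [(p.id, g, prot) for p in pcs for g, prot in p.members],
        columns=["pc", "genome", "protein"],
    ).to_csv(outdir / "pcs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(e.genome_a, e.genome_b, e.shared_pcs, e.p_value, e.score) for e in vc.edges],
        columns=["source", "target", "shared_pcs", "p_value", "score"],
    ).to_csv(outdir / "network_edges.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"vc": pd.Series(vc.membership), "class": pd.Series(vc.classes)}
    ).rename_axis("genome").to_csv(outdir / "vcs.tsv", sep="\t")
    pd.Series(vc.modularity, name="modularity").rename_axis("inflation").to_csv(
        outdir / "inflation_scan.tsv", sep="\t"
    )

    # -- hostlink -------------------------------------------------------------
    arrays = {
        hid: find_crispr_arrays(
            seq,
            host=hid,
            repeat_len_range=config.hostlink.repeat_len_range,
            spacer_len_range=config.hostlink.spacer_len_range,
            min_repeats=config.hostlink.min_repeats,
        )
        for hid, seq in hosts.items()
    }
    links = crispr_links(
        arrays, representatives, max_mismatch=config.hostlink.max_mismatch
    ) + similarity_link(
        representatives,
        hosts,
        min_bitscore=config.hostlink.min_bitscore,
        max_evalue=config.hostlink.max_evalue,
        min_ani=config.hostlink.min_ani,
        min_len=config.hostlink.min_len,
    )
    log.info(
        "stage hostlink: %d arrays, %d links",
        sum(len(a) for a in arrays.values()), len(links),
    )
    pd.DataFrame(
        [(l.votu, l.host, l.evidence) for l in links], columns=["votu", "host", "evidence"]
    ).to_csv(outdir / "host_links.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            (hid, ai, a.repeat, len(a.spacers), a.start, a.end)
            for hid, arrs in arrays.items()
            for ai, a in enumerate(arrs)
        ],
        columns=["host", "array", "repeat", "n_spacers", "start", "end"],
    ).to_csv(outdir / "crispr_arrays.tsv", sep="\t", index=False)

    # -- ecology --------------------------------------------------------------
    div = pd.DataFrame(
        {
            sid: dataclasses.asdict(diversity(scaled.loc[sid][matrix.detected.loc[sid]]))
            for sid in scaled.index
        }
    ).T.rename_axis("sample")
    bc = bray_curtis(scaled)
    ordination = pcoa(bc)
    sharing = habitat_sharing(matrix.detected, sample_habitats)
    curve = collectors_curve(
        matrix.detected, n_randomizations=config.ecology.n_randomizations, seed=config.seed
    )
    folds = habitat_fold_factors(
        matrix.values,
        sample_habitats,
        config.ecology.reference_habitat,
        contig_lengths=lengths,
    )
    codon_seqs = {**representatives, **hosts}
    codon = pd.DataFrame(
        {name: codon_usage_profile({name: seq[: len(seq) - len(seq) % 3]}) for name, seq in codon_seqs.items()}
    ).T
    codon_ord = pcoa(bray_curtis(codon))
    log.info("stage ecology: folds %s", dict(folds.round(2)))

    write_tsv_matrix(div, outdir / "diversity.tsv")
    write_tsv_matrix(bc, outdir / "braycurtis.tsv")
    write_tsv_matrix(ordination.coordinates, outdir / "pcoa_coordinates.tsv")
    pd.Series(
        ordination.proportion_explained,
        index=ordination.coordinates.columns,
        name="variance_fraction",
    ).rename_axis("axis").to_csv(outdir / "pcoa_variance.tsv", sep="\t")
    pd.DataFrame(
        [("+".join(sorted(k)), v) for k, v in sorted(sharing.regions.items(), key=lambda kv: sorted(kv[0]))],
        columns=["region", "n_votus"],
    ).to_csv(outdir / "habitat_regions.tsv", sep="\t", index=False)
    pd.DataFrame(
        {"mean_richness": curve.mean}, index=pd.RangeIndex(1, len(curve.mean) + 1, name="n_samples")
    ).to_csv(outdir / "collector_curve.tsv", sep="\t")
    folds.rename("fold_vs_reference").rename_axis("habitat").to_csv(
        outdir / "habitat_folds.tsv", sep="\t"
    )
    write_tsv_matrix(codon_ord.coordinates, outdir / "codon_pcoa_coordinates.tsv")

    ecology_out = {
        "diversity": div,
        "braycurtis": bc,
        "ordination": ordination,
        "sharing": sharing,
        "collector": curve,
        "folds": folds,
        "codon_ordination": codon_ord,
    }

    # -- manifest -------------------------------------------------------------
    checksums = {}
    for p in sorted(outdir.rglob("*")):
        if p.is_file() and p.name != "manifest.json":
            checksums[str(p.relative_to(outdir))] = hashlib.sha256(p.read_bytes()).hexdigest()
    manifest = {
        "package": "thawvir",
        "version": __version__,
        "seed": config.seed,
        "stages": list(STAGES),
        "parameters": config.to_dict(),
        "outputs": checksums,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")

    return PipelineResult(
        config=config,
        outdir=outdir,
        community=community,
        truth=truth,
        contaminant_refs=refs,
        flagged=flagged,
        votus=votus,
        membership=membership,
        representatives=representatives,
        sample_habitats=sample_habitats,
        sample_total_bp=sample_total_bp,
        abundance=matrix,
        scaled=scaled,
        pcs=pcs,
        profiles=profiles,
        vc_assignment=vc,
        crispr_arrays=arrays,
        host_links=links,
        ecology=ecology_out,
    )
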