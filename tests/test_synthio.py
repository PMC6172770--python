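"""Synthetic community generator: configured structure, determinism, read fidelity."""

import numpy as np
import pytest

from thawvir._align import revcomp
from thawvir.synthio import (
    CommunityConfig,
    ConfigError,
    GeneContentPlan,
    default_gene_plan,
    simulate_community,
    simulate_gene_content,
    simulate_hosts_with_crispr,
    simulate_reads,
)


def config(**kw):
    base = dict(
        habitats=("palsa", "bog", "fen"),
        votus_per_habitat=10,
        overlaps={("palsa", "bog"): 0, ("bog", "fen"): 0, ("palsa", "fen"): 0},
        genome_length_range=(3_000, 5_000),
        seed=11,
    )
    base.update(kw)
    return CommunityConfig(**base)


class TestSimulateCommunity:
    def test_zero_overlap_gives_fully_distinct_pools(self):
        community, truth = simulate_community(config())
        assert len(community.genomes) == 30
        pools = community.habitat_pools
        for a in pools:
            for b in pools:
                if a != b:
                    assert not set(pools[a]) & set(pools[b])

    def test_configured_overlaps_realised_exactly(self):
        cfg = config(overlaps={("bog", "fen"): 4, ("palsa", "fen"): 0, ("palsa", "bog"): 0})
        community, truth = simulate_community(cfg)
        pools = {h: set(p) for h, p in community.habitat_pools.items()}
        assert len(pools["bog"] & pools["fen"]) == 4
        assert len(pools["palsa"] & pools["fen"]) == 0
        # presence table agrees with the pools
        pres = truth.presence
        assert (pres.loc["bog"] & pres.loc["fen"]).sum() == 4

    def test_same_seed_reproduces_identical_output(self):
        c1, t1 = simulate_community(config())
        c2, t2 = simulate_community(config())
        assert c1.genomes == c2.genomes
        assert c1.contigs == c2.contigs
        assert t1.abundance_table.equals(t2.abundance_table)

    def test_changing_seed_preserves_counts(self):
        c1, _ = simulate_community(config(seed=1))
        c2, _ = simulate_community(config(seed=2))
        assert c1.genomes != c2.genomes
        assert len(c1.genomes) == len(c2.genomes)
        assert {h: len(p) for h, p in c1.habitat_pools.items()} == {
            h: len(p) for h, p in c2.habitat_pools.items()
        }

    def test_abundance_rows_sum_to_one(self):
        _, truth = simulate_community(config(overlaps={("palsa", "bog"): 3}))
        np.testing.assert_allclose(truth.abundance_table.sum(axis=1), 1.0, atol=1e-12)

    def test_invalid_overlap_names_offending_pair(self):
        with pytest.raises(ConfigError, match=r"bog.*fen|fen.*bog"):
            simulate_community(config(overlaps={("bog", "fen"): 11}))

    def test_every_contig_traces_to_one_votu(self):
        community, truth = simulate_community(config())
        assert set(truth.votu_memberships) == set(community.contigs)
        assert set(truth.votu_memberships.values()) == set(community.genomes)


class TestSimulateReads:
    def test_error_free_reads_are_exact_substrings(self, random_seq):
        g = {"g1": random_seq(2_000)}
        reads, origin = simulate_reads(g, {"g1": 1.0}, n_reads=200, read_len=80, err_rate=0.0, seed=3)
        for rid, seq in reads:
            strand = origin.loc[rid, "strand"]
            probe = seq if strand == "+" else revcomp(seq)
            assert probe in g["g1"]
            assert g["g1"][origin.loc[rid, "start"] :].startswith(probe)

    def test_read_split_follows_abundance_times_length(self, random_seq):
        # equal lengths, abundances 0.8/0.2 -> binomial(n, 0.8) split
        g = {"a": random_seq(3_000, seed=1), "b": random_seq(3_000, seed=2)}
        n = 50_000
        reads, origin = simulate_reads(g, {"a": 0.8, "b": 0.2}, n_reads=n, read_len=60, seed=9)
        n_a = (origin.genome == "a").sum()
        sd = np.sqrt(n * 0.8 * 0.2)
        assert abs(n_a - 0.8 * n) <= 3 * sd

    def test_error_rate_sets_mean_read_identity(self, random_seq):
        g = {"g1": random_seq(5_000)}
        reads, origin = simulate_reads(g, {"g1": 1.0}, n_reads=2_000, read_len=100, err_rate=0.05, seed=4)
        idents = []
        for rid, seq in reads:
            row = origin.loc[rid]
            ref = g["g1"][row.start : row.start + 100]
            probe = seq if row.strand == "+" else revcomp(seq)
            idents.append(sum(a == b for a, b in zip(probe, ref)) / 100)
        assert abs(np.mean(idents) - 0.95) < 0.005

    def test_both_orientations_drawn(self, random_seq):
        g = {"g1": random_seq(2_000)}
        _, origin = simulate_reads(g, {"g1": 1.0}, n_reads=500, read_len=50, seed=5)
        frac = (origin.strand == "-").mean()
        assert 0.4 < frac < 0.6

    def test_read_longer_than_shortest_genome_rejected(self, random_seq):
        g = {"g1": random_seq(120)}
        with pytest.raises(ValueError, match="read_len"):
            simulate_reads(g, {"g1": 1.0}, n_reads=10, read_len=200)

    def test_abundances_must_sum_to_one(self, random_seq):
        g = {"g1": random_seq(500)}
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_reads(g, {"g1": 0.5}, n_reads=10, read_len=50)


class TestSimulateHosts:
    def test_array_structure_repeats_and_spacers(self, random_seq):
        viral = {"v1": random_seq(4_000, seed=7)}
        hosts, links = simulate_hosts_with_crispr(
            2, viral, spacers_per_array=5, repeat_len=30, spacer_len=32, seed=8,
            host_length=8_000, n_similarity_hosts=0, n_free_hosts=1,
        )
        crispr_host = hosts["host01"]
        spacers = [l.spacer for l in links if l.host == "host01"]
        assert len(spacers) == 5
        assert len(set(spacers)) == 5  # spacers are distinct
        positions = sorted(crispr_host.find(s) for s in spacers)
        assert all(p >= 0 for p in positions)
        # array layout: 6 identical repeats alternate with the 5 spacers
        period = 30 + 32
        assert [b - a for a, b in zip(positions, positions[1:])] == [period] * 4
        repeats = {crispr_host[p - 30 : p] for p in positions}
        repeats.add(crispr_host[positions[-1] + 32 : positions[-1] + 32 + 30])
        assert len(repeats) == 1

    def test_protospacers_verbatim_in_viral_genome(self, random_seq):
        viral = {"v1": random_seq(4_000, seed=1), "v2": random_seq(4_000, seed=2)}
        _, links = simulate_hosts_with_crispr(
            3, viral, seed=5, host_length=6_000, n_similarity_hosts=0, n_free_hosts=0
        )
        for l in links:
            proto = l.spacer if l.strand == "+" else revcomp(l.spacer)
            assert proto in viral[l.virus]

    def test_unlinked_host_shares_no_long_substring_with_viruses(self, random_seq):
        spacer_len = 20
        viral = {"v1": random_seq(2_000, seed=3)}
        hosts, links = simulate_hosts_with_crispr(
            1, viral, spacer_len=spacer_len, seed=6, host_length=3_000,
            n_similarity_hosts=0, n_free_hosts=1,
        )
        assert not links
        free = hosts["host01"]
        vset = {viral["v1"][i : i + spacer_len] for i in range(len(viral["v1"]) - spacer_len + 1)}
        rc = revcomp(viral["v1"])
        vset |= {rc[i : i + spacer_len] for i in range(len(rc) - spacer_len + 1)}
        host_words = {free[i : i + spacer_len] for i in range(len(free) - spacer_len + 1)}
        assert not host_words & vset


class TestSimulateGeneContent:
    def test_family_count_matches_configuration(self):
        plan = default_gene_plan([f"g{i}" for i in range(8)], n_clusters=2, intra_shared=5)
        fams, edges, pg, truth = simulate_gene_content(plan, families_per_genome=12, seed=1)
        assert all(len(f) == 12 for f in fams.values())
        assert len(set(truth.vc_assignments.values())) == 2

    def test_planned_singleton_shares_nothing(self):
        plan = GeneContentPlan(clusters=[["a", "b", "c"], ["z"]], intra_shared=4)
        fams, _, _, _ = simulate_gene_content(plan, families_per_genome=6, seed=2)
        for other in ("a", "b", "c"):
            assert not set(fams["z"]) & set(fams[other])

    def test_inter_ge_intra_rejected(self):
        plan = GeneContentPlan(clusters=[["a"], ["b"]], intra_shared=3, inter_shared=3)
        with pytest.raises(ConfigError, match="inter-cluster"):
            plan.validate()

    def test_edges_connect_only_same_family_proteins(self):
        plan = default_gene_plan([f"g{i}" for i in range(6)], n_clusters=2, intra_shared=4)
        fams, edges, pg, truth = simulate_gene_content(plan, families_per_genome=8, seed=3)
        for q, s in zip(edges["query"], edges["subject"]):
            assert truth.pc_assignments[q] == truth.pc_assignments[s]
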