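"""Hypergeometric scoring, MCL, protein clusters, and viral-cluster assignment."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thawvir.network import (
    DEFAULT_INFLATION_GRID,
    GenomeProfile,
    assign_viral_clusters,
    build_protein_clusters,
    hypergeom_shared_pc_pvalue,
    log_hypergeom_tail,
    mcl,
    shared_pc_edges,
    similarity_score,
)
from thawvir.synthio import default_gene_plan, simulate_gene_content


def enumeration_pvalue(a: int, b: int, c: int, n: int) -> Fraction:
    """Exact tail probability by exhaustive enumeration of draws (oracle)."""
    universe = range(n)
    A = set(range(a))
    hits = sum(1 for B in itertools.combinations(universe, b) if len(A & set(B)) >= c)
    return Fraction(hits, math.comb(n, b))


class TestHypergeometric:
    def test_zero_shared_gives_probability_one(self):
        assert hypergeom_shared_pc_pvalue(3, 3, 0, 10) == 1.0

    def test_small_exact_value(self):
        # n=5, a=3, b=3, c=3: C(3,3)*C(2,0)/C(5,3) = 1/10
        assert hypergeom_shared_pc_pvalue(3, 3, 3, 5) == pytest.approx(0.1, rel=1e-12)

    @pytest.mark.parametrize(
        "a,b,c,n",
        [(4, 5, 2, 9), (3, 7, 3, 12), (6, 6, 4, 11), (2, 2, 1, 4), (5, 5, 5, 10)],
    )
    def test_matches_exhaustive_enumeration(self, a, b, c, n):
        expected = float(enumeration_pvalue(a, b, c, n))
        assert hypergeom_shared_pc_pvalue(a, b, c, n) == pytest.approx(expected, rel=1e-9)

    @given(st.data())
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_symmetric_in_a_and_b(self, data):
        n = data.draw(st.integers(2, 40))
        a = data.draw(st.integers(1, n))
        b = data.draw(st.integers(1, n))
        c = data.draw(st.integers(0, min(a, b)))
        assert hypergeom_shared_pc_pvalue(a, b, c, n) == pytest.approx(
            hypergeom_shared_pc_pvalue(b, a, c, n), rel=1e-9
        )

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_shared_pc_pvalue(3, 3, 4, 10)
        with pytest.raises(ValueError):
            hypergeom_shared_pc_pvalue(11, 3, 1, 10)

    def test_log_tail_survives_underflow(self):
        # a tail below double-precision underflow stays finite in log space
        logp = log_hypergeom_tail(600, 600, 600, 1200)
        assert np.isfinite(logp) and logp < -780  # exp(logp) would underflow to 0
        s = similarity_score(None, 2052, log10_p=logp / math.log(10))
        assert np.isfinite(s) and s > 100


class TestSimilarityScore:
    def test_p_one_gives_negative_score(self):
        assert similarity_score(1.0, 100) < 0

    def test_published_network_scale_arithmetic(self):
        # 2,052 genomes -> T = 2,052 x 2,051 ordered comparisons
        s = similarity_score(1e-8, 2052)
        assert s == pytest.approx(8 - math.log10(2052 * 2051), abs=1e-9)
        assert s == pytest.approx(1.376, abs=0.001)

    @pytest.mark.parametrize("n", [10, 100, 2052])
    def test_edge_boundary_algebra(self, n):
        # S >= 1 exactly when p <= 0.1 / T
        T = n * (n - 1)
        assert similarity_score(0.1 / T, n) == pytest.approx(1.0, abs=1e-9)
        assert similarity_score(0.11 / T, n) < 1.0
        assert similarity_score(0.09 / T, n) > 1.0

    def test_literal_zero_p_rejected(self):
        with pytest.raises(ValueError, match="log10_p"):
            similarity_score(0.0, 10)


def reference_mcl(A, inflation, max_iter=200, tol=1e-10):
    """Naive dense MCL written independently of the library implementation."""
    M = [[float(A[i][j]) for j in range(len(A))] for i in range(len(A))]
    n = len(M)
    for i in range(n):
        M[i][i] = 0.0
    for i in range(n):
        M[i][i] = max(1.0, max(M[k][i] for k in range(n)))
    # column normalise
    def norm(mat):
        for j in range(n):
            s = sum(mat[i][j] for i in range(n))
            if s:
                for i in range(n):
                    mat[i][j] /= s
        return mat

    M = norm(M)
    for _ in range(max_iter):
        sq = [[sum(M[i][k] * M[k][j] for k in range(n)) for j in range(n)] for i in range(n)]
        infl = [[sq[i][j] ** inflation for j in range(n)] for i in range(n)]
        infl = norm(infl)
        delta = max(abs(infl[i][j] - M[i][j]) for i in range(n) for j in range(n))
        M = infl
        if delta < tol:
            break
    clusters = []
    assigned = set()
    for i in range(n):
        if M[i][i] > 1e-6 and i not in assigned:
            grp = {j for j in range(n) if M[i][j] > 1e-6}
            for existing in clusters:
                if grp & existing:
                    existing |= grp
                    break
            else:
                clusters.append(set(grp))
            assigned |= grp
    for i in range(n):
        if not any(i in g for g in clusters):
            clusters.append({i})
    return sorted(map(frozenset, clusters), key=min)


class TestMcl:
    @pytest.mark.parametrize("inflation", [1.2, 2.0, 5.0])
    def test_two_cliques_split(self, inflation):
        A = np.zeros((8, 8))
        A[:4, :4] = 1
        A[4:, 4:] = 1
        np.fill_diagonal(A, 0)
        assert mcl(A, inflation=inflation) == [frozenset(range(4)), frozenset(range(4, 8))]

    def test_idempotent_stochastic_fixed_point(self):
        # block-diagonal uniform stochastic matrix is an MCL fixed point
        A = np.zeros((4, 4))
        A[:2, :2] = 1
        A[2:, 2:] = 1
        out = mcl(A, inflation=2.0)
        assert out == [frozenset({0, 1}), frozenset({2, 3})]

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_independent_reference_on_random_two_block_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = 20
        A = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                same = (i < n // 2) == (j < n // 2)
                p = 0.8 if same else 0.05
                if rng.random() < p:
                    A[i, j] = A[j, i] = rng.uniform(0.5, 2.0)
        ours = mcl(A, inflation=2.0)
        ref = reference_mcl(A.tolist(), inflation=2.0)
        assert ours == ref

    def test_non_symmetric_rejected(self):
        A = np.array([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            mcl(A)

    def test_isolated_nodes_are_singletons(self):
        A = np.zeros((3, 3))
        A[0, 1] = A[1, 0] = 1.0
        assert mcl(A, inflation=2.0) == [frozenset({0, 1}), frozenset({2})]


class TestProteinClusters:
    def edges(self, families):
        rows = []
        for fam in families:
            for p, q in itertools.combinations(fam, 2):
                rows.append((p, q, 100.0, 1e-20))
        return pd.DataFrame(rows, columns=["query", "subject", "bitscore", "evalue"])

    def test_two_families_give_two_pcs(self):
        fams = [[f"gA|p{i}" for i in range(5)], [f"gB|q{i}" for i in range(5)]]
        pg = {p: ("g1" if i % 2 else "g2") for fam in fams for i, p in enumerate(fam)}
        pcs, profiles = build_protein_clusters(self.edges(fams), pg)
        assert len(pcs) == 2

    def test_single_genome_family_demoted(self):
        fams = [["g1|a", "g1|b", "g1|c"]]
        pg = {"g1|a": "g1", "g1|b": "g1", "g1|c": "g1"}
        pcs, profiles = build_protein_clusters(self.edges(fams), pg)
        assert pcs == []
        assert profiles[0].pc_set == frozenset()
        assert profiles[0].singleton_count == 3

    def test_threshold_filtering_drops_weak_edges(self):
        df = pd.DataFrame(
            [("a|1", "b|1", 100.0, 1e-20), ("a|2", "b|2", 30.0, 1e-20),
             ("a|3", "b|3", 100.0, 1e-2)],
            columns=["query", "subject", "bitscore", "evalue"],
        )
        pg = {p: p.split("|")[0] for p in ["a|1", "a|2", "a|3", "b|1", "b|2", "b|3"]}
        pcs, _ = build_protein_clusters(df, pg)
        members = {m for pc in pcs for _, m in pc.members}
        assert members == {"a|1", "b|1"}

    def test_self_edges_ignored_with_warning(self):
        df = pd.DataFrame([("a|1", "a|1", 100.0, 1e-20)],
                          columns=["query", "subject", "bitscore", "evalue"])
        with pytest.warns(UserWarning, match="self-edges"):
            build_protein_clusters(df, {"a|1": "a"})

    def test_recovers_planted_families(self):
        plan = default_gene_plan([f"g{i}" for i in range(8)], n_clusters=2, intra_shared=6)
        fams, edges, pg, truth = simulate_gene_content(plan, families_per_genome=10, seed=4)
        pcs, _ = build_protein_clusters(edges, pg)
        recovered = {frozenset(p for _, p in pc.members) for pc in pcs}
        planted = {}
        for prot, fam in truth.pc_assignments.items():
            planted.setdefault(fam, set()).add(prot)
        multi_genome = {
            frozenset(m) for m in planted.values()
            if len({pg[p] for p in m}) >= 2
        }
        assert recovered == multi_genome


def profile(g, pcs):
    return GenomeProfile(genome=g, pc_set=frozenset(pcs))


class TestViralClusters:
    def make_profiles(self):
        # two planted clusters with disjoint PC content plus one empty genome
        pcs1 = [f"PC{i}" for i in range(8)]
        pcs2 = [f"QC{i}" for i in range(8)]
        profs = [profile(f"a{i}", pcs1) for i in range(3)]
        profs += [profile(f"b{i}", pcs2) for i in range(3)]
        profs.append(profile("lonely", []))
        return profs

    def test_grid_has_21_values(self):
        assert len(DEFAULT_INFLATION_GRID) == 21
        assert DEFAULT_INFLATION_GRID[0] == 1.0
        assert DEFAULT_INFLATION_GRID[-1] == 5.0

    def test_planted_two_cluster_plan_recovered_at_every_inflation(self):
        vc = assign_viral_clusters(self.make_profiles())
        for inf, part in vc.partitions.items():
            non_single = [p for p in part if len(p) > 1]
            assert sorted(sorted(p) for p in non_single) == [
                ["a0", "a1", "a2"], ["b0", "b1", "b2"]
            ]
        assert vc.classes["a0"] == "clustered"
        assert vc.classes["lonely"] == "singleton"

    def test_doubleton_classification(self):
        shared = [f"P{i}" for i in range(10)]
        profs = [profile("x", shared), profile("y", shared)]
        profs += [profile(f"z{i}", [f"Z{j}" for j in range(10)]) for i in range(3)]
        vc = assign_viral_clusters(profs)
        assert vc.classes["x"] == "doubleton"
        assert vc.classes["y"] == "doubleton"
        assert vc.classes["z0"] == "clustered"

    def test_empty_profile_does_not_perturb_edges(self):
        profs = self.make_profiles()
        base = shared_pc_edges(profs, n_genomes=50)
        withempty = shared_pc_edges(profs + [profile("ghost", [])], n_genomes=50)
        assert base == withempty

    def test_scores_invariant_under_pc_relabeling(self):
        profs = self.make_profiles()
        relabel = {f"PC{i}": f"XX{i}" for i in range(8)}
        relabeled = [
            GenomeProfile(p.genome, frozenset(relabel.get(x, x) for x in p.pc_set))
            for p in profs
        ]
        s1 = {(e.genome_a, e.genome_b): e.score for e in shared_pc_edges(profs)}
        s2 = {(e.genome_a, e.genome_b): e.score for e in shared_pc_edges(relabeled)}
        assert s1 == s2

    def test_empty_network_all_singletons_with_warning(self):
        profs = [profile("a", ["P1"]), profile("b", ["P2"])]
        with pytest.warns(UserWarning, match="singleton"):
            vc = assign_viral_clusters(profs)
        assert set(vc.classes.values()) == {"singleton"}
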