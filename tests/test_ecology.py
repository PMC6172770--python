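"""Diversity, Bray-Curtis, PCoA, collector curves, habitat sharing, codon usage."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thawvir.ecology import (
    bray_curtis,
    codon_usage_profile,
    collectors_curve,
    diversity,
    habitat_sharing,
    pcoa,
    screen_contaminants,
)
from thawvir.synthio import mutate, random_sequence


class TestDiversity:
    def test_uniform_community(self):
        d = diversity([0.1] * 10)
        assert d.richness == 10
        assert d.shannon == pytest.approx(np.log(10))
        assert d.pielou == pytest.approx(1.0)

    def test_single_taxon(self):
        d = diversity([5.0, 0.0, 0.0])
        assert (d.richness, d.shannon, d.pielou) == (1, 0.0, 0.0)

    def test_closed_form_value(self):
        d = diversity([0.5, 0.3, 0.2])
        expected = -(0.5 * np.log(0.5) + 0.3 * np.log(0.3) + 0.2 * np.log(0.2))
        assert d.shannon == pytest.approx(expected)  # 1.02965...
        assert d.shannon == pytest.approx(1.02965, abs=1e-5)

    def test_all_zero_row(self):
        d = diversity([0.0, 0.0])
        assert (d.richness, d.shannon, d.pielou) == (0, 0.0, 0.0)

    def test_invariant_to_prescaling(self):
        raw = [3.0, 1.0, 6.0, 0.5]
        a, b = diversity(raw), diversity([x * 37.5 for x in raw])
        assert a.shannon == pytest.approx(b.shannon)
        assert a.pielou == pytest.approx(b.pielou)

    def test_configurable_base(self):
        d = diversity([0.25] * 4, base=2)
        assert d.shannon == pytest.approx(2.0)
        assert d.pielou == pytest.approx(1.0)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        m = pd.DataFrame([[1.0, 2.0], [1.0, 2.0]])
        assert bray_curtis(m).iloc[0, 1] == 0.0

    def test_disjoint_support_one(self):
        m = pd.DataFrame([[1.0, 0.0], [0.0, 3.0]])
        assert bray_curtis(m).iloc[0, 1] == 1.0

    def test_arithmetic_example(self):
        m = pd.DataFrame([[1.0, 2.0, 0.0], [0.0, 2.0, 2.0]])
        assert bray_curtis(m).iloc[0, 1] == pytest.approx(3 / 7)

    def test_zero_row_pair_defined_zero_with_warning(self):
        m = pd.DataFrame([[0.0, 0.0], [0.0, 0.0], [1.0, 1.0]])
        with pytest.warns(UserWarning, match="all-zero"):
            D = bray_curtis(m)
        assert D.iloc[0, 1] == 0.0

    @given(st.lists(st.lists(st.floats(0, 100), min_size=4, max_size=4),
                    min_size=3, max_size=5))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_symmetric_zero_diagonal_bounded(self, rows):
        m = pd.DataFrame(rows) + 0.01  # avoid all-zero pairs
        D = bray_curtis(m).to_numpy()
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0)
        assert (D >= 0).all() and (D <= 1 + 1e-12).all()


class TestPcoa:
    def test_collinear_points_single_axis(self):
        D = np.array([[0.0, 1.0, 2.0], [1.0, 0.0, 1.0], [2.0, 1.0, 0.0]])
        res = pcoa(D)
        assert res.proportion_explained[0] == pytest.approx(1.0)

    def test_recovers_planted_euclidean_configuration(self):
        rng = np.random.default_rng(17)
        X = rng.normal(size=(12, 2))
        D = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))
        res = pcoa(D)
        Y = res.coordinates.to_numpy()[:, :2]
        # Procrustes: optimal rotation/reflection of Y onto centred X
        Xc = X - X.mean(0)
        U, _, Vt = np.linalg.svd(Xc.T @ Y)
        R = (U @ Vt).T
        err = np.abs(Y @ R - Xc).max()
        assert err < 1e-8

    def test_matches_skbio_variance_fractions(self):
        from skbio.stats.ordination import pcoa as skbio_pcoa

        rng = np.random.default_rng(18)
        X = rng.random((6, 4))
        m = pd.DataFrame(X)
        D = bray_curtis(m)
        ours = pcoa(D)
        ref = skbio_pcoa(D.to_numpy(), number_of_dimensions=0)
        n = len(ours.proportion_explained)
        # conventions differ by a constant: skbio divides by sum(positive
        # eigenvalues) while we divide by sum(positive) + |sum(negative)|;
        # the eigenvalue ratios must agree exactly
        np.testing.assert_allclose(
            ours.proportion_explained / ours.proportion_explained.sum(),
            ref.proportion_explained.to_numpy()[:n]
            / ref.proportion_explained.to_numpy()[:n].sum(),
            atol=1e-8,
        )
        np.testing.assert_allclose(
            ours.eigenvalues, ref.eigvals.to_numpy()[:n], atol=1e-8
        )

    def test_fractions_valid(self):
        rng = np.random.default_rng(19)
        m = pd.DataFrame(rng.random((5, 6)))
        res = pcoa(bray_curtis(m))
        assert (res.proportion_explained >= 0).all()
        assert res.proportion_explained.sum() <= 1 + 1e-9

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            pcoa(np.array([[0.0, 1.0], [2.0, 0.0]]))


class TestCollectorsCurve:
    def test_identical_samples_flat_curve(self):
        P = pd.DataFrame([[1, 1, 0, 1]] * 5).astype(bool)
        res = collectors_curve(P, n_randomizations=10, seed=1)
        assert np.all(res.mean == 3)

    def test_disjoint_samples_linear_curve(self):
        P = pd.DataFrame(np.eye(4, dtype=bool))
        res = collectors_curve(P, n_randomizations=20, seed=2)
        np.testing.assert_allclose(res.mean, [1, 2, 3, 4])

    def test_monotone_and_final_value_exact(self):
        rng = np.random.default_rng(3)
        P = pd.DataFrame(rng.random((6, 30)) < 0.3)
        res = collectors_curve(P, n_randomizations=25, seed=4)
        assert np.all(np.diff(res.curves, axis=1) >= 0)
        total = P.any(axis=0).sum()
        assert np.all(res.curves[:, -1] == total)

    def test_seed_stability_at_200_randomizations(self):
        rng = np.random.default_rng(5)
        P = pd.DataFrame(rng.random((7, 60)) < 0.4)
        m1 = collectors_curve(P, n_randomizations=200, seed=10).mean
        m2 = collectors_curve(P, n_randomizations=200, seed=11).mean
        # Monte-Carlo tolerance: per-step spread / sqrt(200), generous factor
        sd = collectors_curve(P, 200, seed=10).curves.std(axis=0)
        tol = 4 * sd / np.sqrt(200) + 1e-9
        assert np.all(np.abs(m1 - m2) <= tol)


class TestHabitatSharing:
    def make_presence(self):
        taxa = [f"t{i}" for i in range(10)]
        P = pd.DataFrame(False, index=["s1", "s2", "s3"], columns=taxa)
        P.loc["s1", ["t0", "t1", "t2", "t3"]] = True  # bog
        P.loc["s2", ["t2", "t3", "t4", "t5"]] = True  # fen
        P.loc["s3", ["t6", "t7"]] = True  # palsa
        return P

    def test_pairwise_counts_and_regions(self):
        sh = habitat_sharing(
            self.make_presence(), {"s1": "bog", "s2": "fen", "s3": "palsa"}
        )
        assert sh.pairwise_shared.loc["bog", "fen"] == 2
        assert sh.pairwise_shared.loc["palsa", "fen"] == 0
        assert sh.regions[frozenset({"bog", "fen"})] == 2
        assert sum(sh.regions.values()) == 8  # partition of detected taxa
        assert sh.multi_habitat_fraction == pytest.approx(2 / 8)

    def test_all_shared_gives_full_multi_fraction(self):
        P = pd.DataFrame(True, index=["a", "b"], columns=["t1", "t2"])
        sh = habitat_sharing(P, {"a": "x", "b": "y"})
        assert sh.multi_habitat_fraction == 1.0

    def test_unlabeled_sample_rejected(self):
        with pytest.raises(ValueError, match="habitat label"):
            habitat_sharing(self.make_presence(), {"s1": "bog"})


class TestCodonUsage:
    def test_single_codon_sequence(self):
        prof = codon_usage_profile(["ATGATGATG"])
        assert prof["ATG"] == 1.0
        assert prof.sum() == 1.0

    def test_sums_to_one_for_random_cds(self):
        rng = np.random.default_rng(6)
        seqs = [random_sequence(rng, 3 * int(rng.integers(50, 200))) for _ in range(5)]
        assert codon_usage_profile(seqs).sum() == pytest.approx(1.0, abs=1e-12)

    def test_concatenation_equals_length_weighted_mean(self):
        rng = np.random.default_rng(7)
        a = random_sequence(rng, 300)
        b = random_sequence(rng, 900)
        combined = codon_usage_profile([a + b])
        weighted = (codon_usage_profile([a]) * 100 + codon_usage_profile([b]) * 300) / 400
        pd.testing.assert_series_equal(combined, weighted)

    def test_bad_length_names_sequence(self):
        with pytest.raises(ValueError, match="cds_x"):
            codon_usage_profile({"cds_x": "ATGA"})


class TestScreenContaminants:
    def test_copied_contig_flagged(self):
        rng = np.random.default_rng(8)
        ref = random_sequence(rng, 5_000)
        contigs = {"clean": random_sequence(rng, 5_000), "dirty": mutate(ref, 0.02, rng)}
        assert screen_contaminants(contigs, {"ref": ref}) == ["dirty"]

    def test_distant_contig_not_flagged(self):
        rng = np.random.default_rng(9)
        ref = random_sequence(rng, 5_000)
        distant = mutate(ref, 0.10, rng)  # ~90% ANI
        assert screen_contaminants({"c": distant}, {"ref": ref}) == []

    def test_empty_reference_set(self):
        assert screen_contaminants({"c": "ACGT" * 300}, {}) == []
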