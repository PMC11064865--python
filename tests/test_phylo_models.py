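"""Likelihoods, tree priors, site models, and parameter transforms."""

import math

import numpy as np
import pytest

from cubevb.phylo_models import (
    Alignment,
    PruningEngine,
    SiteModel,
    TreePrior,
    gtr_model,
    hky_model,
    stick_breaking_forward,
    stick_breaking_inverse,
    transition_matrices,
    tree_log_likelihood,
    tree_prior_log_density,
)
from cubevb.treespace import TreeMatrix, single_link_tree

from conftest import cherry, three_taxon


class TestAlignment:
    def test_ragged_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            Alignment(["a", "b"], ["ACGT", "ACG"])

    def test_pattern_compression_counts(self):
        aln = Alignment(["a", "b"], ["AACA", "AGCA"])
        _, w = aln.compress()
        assert sorted(w) == [1, 1, 2]

    def test_ambiguity_codes_partial_vectors(self):
        aln = Alignment(["a"], ["RN-"])
        sv = aln.state_vectors()[0]
        np.testing.assert_array_equal(sv[0], [1, 0, 1, 0])  # R = A/G
        np.testing.assert_array_equal(sv[1], [1, 1, 1, 1])  # N
        np.testing.assert_array_equal(sv[2], [1, 1, 1, 1])  # gap


class TestLikelihood:
    def test_jc_two_taxon_closed_form(self):
        # P(same) = 1/4 + 3/4 e^{-4t/3}; P(diff) = 1/4 - 1/4 e^{-4t/3}
        t = 0.37
        T = cherry(height=t / 2)
        for seqs, prob in ((["A", "A"], 0.25 + 0.75 * math.exp(-4 * t / 3)),
                           (["A", "C"], 0.25 - 0.25 * math.exp(-4 * t / 3))):
            ll = tree_log_likelihood(Alignment(["A", "B"], seqs), T, hky_model(1.0))
            assert ll == pytest.approx(math.log(0.25 * prob), abs=1e-12)

    def test_zero_height_identical_site(self):
        T = single_link_tree(TreeMatrix(2, {(0, 1): 1e-13}, taxa=["A", "B"]))
        ll = tree_log_likelihood(Alignment(["A", "B"], ["G", "G"]), T, hky_model(3.0))
        assert ll == pytest.approx(math.log(0.25), abs=1e-9)

    def test_hky_kappa_one_equals_jc_transition_matrix(self):
        P = transition_matrices(hky_model(1.0).eigen(), np.array([0.8]))[0]
        same = 0.25 + 0.75 * math.exp(-4 * 0.8 / 3)
        diff = 0.25 - 0.25 * math.exp(-4 * 0.8 / 3)
        expected = np.full((4, 4), diff)
        np.fill_diagonal(expected, same)
        np.testing.assert_allclose(P, expected, atol=1e-12)

    def test_site_order_invariance(self, rng):
        T = three_taxon(0.3, 0.8)
        seqs = ["ACGGTAC", "ACGTTAA", "GCGGTCC"]
        aln = Alignment(list("ABC"), seqs)
        perm = rng.permutation(7)
        aln2 = Alignment(list("ABC"), ["".join(s[i] for i in perm) for s in seqs])
        m = hky_model(2.5, (0.3, 0.2, 0.3, 0.2))
        assert tree_log_likelihood(aln, T, m) == pytest.approx(
            tree_log_likelihood(aln2, T, m), abs=1e-12
        )

    def test_deterministic_reevaluation(self):
        T = three_taxon()
        aln = Alignment(list("ABC"), ["ACGT", "ACGA", "GCGT"])
        m = gtr_model({"AC": 0.7, "AG": 2.0, "AT": 0.4, "CG": 0.6, "CT": 1.0, "GT": 0.9},
                      (0.26, 0.24, 0.25, 0.25))
        s = SiteModel(shape=0.4)
        a = tree_log_likelihood(aln, T, m, s)
        b = tree_log_likelihood(aln, T, m, s)
        assert a == b

    def test_gamma_limit_approaches_homogeneous(self):
        T = three_taxon(0.2, 0.6)
        aln = Alignment(list("ABC"), ["ACGTTGCA", "ACTTTGCA", "GCGTAGCA"])
        m = hky_model(2.0)
        base = tree_log_likelihood(aln, T, m, SiteModel(shape=None))
        big = tree_log_likelihood(aln, T, m, SiteModel(shape=5e4))
        assert big == pytest.approx(base, abs=1e-4)

    def test_mismatched_taxa_rejected(self):
        T = three_taxon()
        aln = Alignment(["A", "B", "X"], ["A", "A", "A"])
        with pytest.raises(ValueError, match="taxa"):
            tree_log_likelihood(aln, T, hky_model(2.0))

    def test_clock_rate_scales_branches(self):
        aln = Alignment(["A", "B"], ["ACCGT", "ATCGA"])
        a = tree_log_likelihood(aln, cherry(height=1.0), hky_model(1.0), clock_rate=0.5)
        b = tree_log_likelihood(aln, cherry(height=0.5), hky_model(1.0), clock_rate=1.0)
        assert a == pytest.approx(b, abs=1e-12)


class TestSiteModel:
    def test_category_rates_mean_one(self):
        for a in (0.1, 0.5, 1.0, 3.0):
            r = SiteModel(shape=a).category_rates()
            assert len(r) == 4
            assert r.mean() == pytest.approx(1.0, abs=1e-10)
            assert np.all(np.diff(r) > 0)


class TestTreePriors:
    def test_coalescent_two_taxon_closed_form(self):
        T = cherry(height=0.9)
        lp = tree_prior_log_density(T, TreePrior("coalescent", pop_size=1.5))
        assert lp == pytest.approx(-math.log(1.5) - 0.9 / 1.5, abs=1e-12)

    def test_yule_ratio_under_height_change(self):
        lam, delta = 4.0, 0.11
        a = three_taxon(0.5, 2.0)
        b = three_taxon(0.5 + delta, 2.0)
        prior = TreePrior("yule", birth_rate=lam)
        # moving an internal node up by delta adds 2*delta of branch below it
        # and removes delta above it: net branch-length change +delta
        ratio = tree_prior_log_density(b, prior) - tree_prior_log_density(a, prior)
        assert ratio == pytest.approx(-lam * delta, abs=1e-12)

    def test_relabelling_invariance(self):
        prior = TreePrior("yule", birth_rate=2.0)
        a = three_taxon(0.5, 2.0, taxa=("A", "B", "C"))
        b = three_taxon(0.5, 2.0, taxa=("C", "A", "B"))
        assert tree_prior_log_density(a, prior) == tree_prior_log_density(b, prior)


class TestStickBreaking:
    def test_uniform_maps_to_origin(self):
        np.testing.assert_allclose(
            stick_breaking_forward(np.full(4, 0.25)), 0.0, atol=1e-12
        )
        np.testing.assert_allclose(
            stick_breaking_inverse(np.zeros(3)), 0.25, atol=1e-12
        )

    def test_roundtrip_dirichlet_draws(self, rng):
        X = rng.dirichlet([1.0] * 4, size=1000)
        err = max(
            np.abs(stick_breaking_inverse(stick_breaking_forward(x)) - x).max()
            for x in X
        )
        assert err < 1e-10

    def test_zero_component_rejected(self):
        with pytest.raises(ValueError):
            stick_breaking_forward(np.array([0.0, 0.5, 0.25, 0.25]))


def test_pruning_engine_agrees_with_itself_on_patterns(rng):
    """Compressed-pattern likelihood equals an explicit per-site sum."""
    from cubevb.synthetic_data import simulate_alignment, simulate_yule

    T = simulate_yule(6, 4.0, rng)
    aln = simulate_alignment(T, hky_model(3.0), length=40, rng=rng)
    eng = PruningEngine(aln)
    full = eng.log_likelihood(T, hky_model(3.0))
    per_site = sum(
        PruningEngine(Alignment(aln.taxa, [s[i] for s in aln.sequences]))
        .log_likelihood(T, hky_model(3.0))
        for i in range(aln.length)
    )
    assert full == pytest.approx(per_site, abs=1e-8)
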