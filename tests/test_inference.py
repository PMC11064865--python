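"""UPGMA, simulated annealing, cube-restricted MCMC, and the variational fit."""

import math
from collections import Counter

import numpy as np
import pytest
from scipy.stats import chisquare, ks_2samp

from cubevb.inference import (
    AnnealingSchedule,
    ChainState,
    PhyloPosterior,
    VariationalPosterior,
    cube_narrow_exchange,
    cube_subtree_slide,
    find_map_state,
    fit_variational,
    jc_distance_matrix,
    mcmc_trees,
    run_cube_mcmc,
    simulated_annealing,
    upgma_tree,
)
from cubevb.phylo_models import Alignment
from cubevb.synthetic_data import simulate_alignment, simulate_yule, yule_hky_design
from cubevb.phylo_models import hky_model
from cubevb.treespace import is_cube_compatible


def prior_only_model(n: int, taxa=None, **kw) -> PhyloPosterior:
    """All-ambiguous alignment: the likelihood is constant, so the chain
    samples the prior."""
    taxa = taxa or [f"t{i}" for i in range(n)]
    return PhyloPosterior(Alignment(taxa, ["N"] * n), **kw)


class TestUpgma:
    def test_two_taxa_half_distance(self):
        T = upgma_tree(np.array([[0.0, 1.2], [1.2, 0.0]]), ["A", "B"])
        assert T.root_height == pytest.approx(0.6)

    def test_three_taxon_hand_execution(self):
        D = np.array([[0, 2.0, 4.0], [2.0, 0, 4.0], [4.0, 4.0, 0]])
        T = upgma_tree(D, list("ABC"))
        clades = {m: T.height[v] for v, m in T.clades().items()}
        assert clades[0b011] == pytest.approx(1.0)
        assert clades[0b111] == pytest.approx(2.0)

    def test_identical_sequences_degenerate(self):
        aln = Alignment(list("ABCD"), ["ACGT"] * 4)
        T = upgma_tree(jc_distance_matrix(aln), aln.taxa)
        T.validate()  # ties resolved into a strictly ordered tree
        assert T.root_height < 1e-6


class TestSimulatedAnnealing:
    def test_quadratic_recovers_argmax(self, rng):
        target = lambda x: -((x - 2.5) ** 2)
        propose = lambda x, r: x + 0.3 * r.standard_normal()
        sched = AnnealingSchedule(start=1.0, end=0.001, repeats=5, steps_per_segment=400)
        best, _ = simulated_annealing(8.0, target, propose, sched, rng)
        assert best == pytest.approx(2.5, abs=0.05)

    def test_flat_target_returns_valid_state(self, rng):
        best, lp = simulated_annealing(
            1.0, lambda x: 0.0, lambda x, r: x + r.standard_normal(),
            AnnealingSchedule(steps_per_segment=10, repeats=2), rng)
        assert lp == 0.0

    def test_infinite_init_raises(self, rng):
        with pytest.raises(ValueError):
            simulated_annealing(0.0, lambda x: -math.inf, lambda x, r: x,
                                AnnealingSchedule(), rng)


class TestCubeOperators:
    def test_slide_same_topology_is_pure_height_change(self, rng):
        state = ChainState([0, 1, 2], np.array([1.0, 2.0]), {})
        for _ in range(50):
            new, log_hr = cube_subtree_slide(state, rng, window=0.01)
            changed = np.flatnonzero(new.h != state.h)
            assert len(changed) == 1
            i = changed[0]
            assert log_hr == pytest.approx(math.log(new.h[i] / state.h[i]), abs=1e-12)

    def test_slide_never_leaves_cube(self, rng):
        """Decoded proposals always re-encode under the fixed ordering."""
        taxa = [f"t{i}" for i in range(8)]
        state = ChainState(list(range(8)), rng.uniform(0.2, 2.0, 7), {})
        for _ in range(2000):
            out = cube_subtree_slide(state, rng, window=2.0)
            state = out[0]
            assert np.all(state.h > 0)
        assert is_cube_compatible(state.tree(taxa), state.pi)

    def test_narrow_exchange_three_taxon_toggles_reachable_topologies(self, rng):
        taxa = list("ABC")
        state = ChainState([0, 1, 2], np.array([1.0, 2.0]), {})
        keys = {state.tree(taxa).topology_key()}
        for _ in range(300):
            out = cube_narrow_exchange(state, rng)
            if out is None:
                continue
            state = out[0]
            keys.add(state.tree(taxa).topology_key())
            assert is_cube_compatible(state.tree(taxa), state.pi)
        # exactly the two cube topologies: ((A,B),C) and (A,(B,C))
        assert len(keys) == 2

    def test_narrow_exchange_reversible(self, rng):
        state = ChainState(list(range(5)), rng.uniform(0.3, 2.0, 4), {})
        taxa = [f"t{i}" for i in range(5)]
        key = state.tree(taxa).topology_key()
        for _ in range(200):
            out = cube_narrow_exchange(state, rng)
            if out is None:
                continue
            mid, fwd = out
            # some later proposal from the new state restores the topology
            restored = False
            for _ in range(200):
                back = cube_narrow_exchange(mid, rng)
                if back is not None and back[0].tree(taxa).topology_key() == key:
                    restored = True
                    break
            assert restored
            break


class TestPriorSampling:
    def test_cube_restricted_topologies_match_restricted_prior(self, rng):
        """Prior-only 3-taxon cube chain: the two reachable topologies are
        equiprobable under the Yule prior restricted to the cube."""
        model = prior_only_model(3, taxa=list("ABC"))
        state = ChainState([0, 1, 2], np.array([0.1, 0.2]),
                           {"kappa": math.e, "birthRate": 6.0})
        res = run_cube_mcmc(model, state, 40000, rng, n_samples=1000)
        counts = Counter(
            t.topology_key() for t in mcmc_trees(res, list("ABC"))
        )
        assert len(counts) == 2
        _, p = chisquare(list(counts.values()))
        assert p > 1e-3

    def test_cube_restricted_heights_match_rejection_oracle(self, rng):
        """Root heights under the cube-restricted prior equal those of
        rejection-sampled Yule trees that happen to fit the cube."""
        model = prior_only_model(3, taxa=list("ABC"))
        init = ChainState([0, 1, 2], np.array([0.1, 0.2]),
                          {"kappa": math.e, "birthRate": 6.0})
        res = run_cube_mcmc(model, init, 40000, rng, n_samples=800)
        chain_heights = res["h"].max(axis=1)
        oracle = []
        while len(oracle) < 2000:
            lam = rng.normal(6.0, 0.1)
            T = simulate_yule(3, lam, rng, taxa=list("ABC"))
            if is_cube_compatible(T, [0, 1, 2]):
                oracle.append(T.root_height)
        D = ks_2samp(chain_heights, oracle).statistic
        assert D < 0.08

    def test_unrestricted_topologies_uniform_over_ranked_histories(self, rng):
        """Prior-only unrestricted chain on 4 taxa: caterpillar topologies
        carry 1/18 mass each, balanced topologies 2/18 (ranked histories)."""
        model = prior_only_model(4)
        T0 = simulate_yule(4, 6.0, rng)
        init = model.init_state(T0, rng)
        res = run_cube_mcmc(model, init, 60000, rng, restrict=False, n_samples=1500)
        trees = mcmc_trees(res, model.taxa)
        counts = Counter()
        balanced = 0
        for t in trees:
            key = t.topology_key()
            counts[key] += 1
            sizes = sorted(bin(m).count("1") for m in t.clades().values())
            if sizes == [2, 2, 4]:
                balanced += 1
        assert len(counts) == 15
        # balanced topologies have two ranked histories each: 6/18 in total
        frac = balanced / len(trees)
        assert abs(frac - 1 / 3) < 0.06

    def test_kappa_prior_recovered_through_proposals(self, rng):
        """Parameter moves + Jacobians leave the lognormal prior invariant."""
        model = prior_only_model(4)
        init = model.init_state(simulate_yule(4, 6.0, rng), rng)
        res = run_cube_mcmc(model, init, 30000, rng, n_samples=1000)
        logk = np.log([p["kappa"] for p in res["params"]])
        oracle = rng.normal(1.0, 1.25, size=3000)
        assert ks_2samp(logk, oracle).statistic < 0.09


class TestMapSearch:
    def test_map_beats_truth_on_simulated_data(self, rng):
        hits = 0
        for _ in range(3):
            T = simulate_yule(4, 6.0, rng)
            aln = simulate_alignment(T, hky_model(3.0), length=300, rng=rng)
            model = PhyloPosterior(aln)
            init = model.init_state(
                upgma_tree(jc_distance_matrix(aln), aln.taxa), rng)
            _, best_lp = find_map_state(
                model, init, AnnealingSchedule(steps_per_segment=120), rng)
            true_state = model.init_state(T, rng)
            true_state.params["kappa"] = 3.0
            true_lp, _ = model.evaluate(true_state)
            if best_lp >= true_lp:
                hits += 1
        assert hits >= 2


class TestMcmcAndFit:
    def test_every_sample_stays_in_cube(self, rng):
        T = simulate_yule(6, 6.0, rng)
        aln = simulate_alignment(T, hky_model(2.0), length=100, rng=rng)
        model = PhyloPosterior(aln)
        init = model.init_state(T, rng)
        res = run_cube_mcmc(model, init, 4000, rng, n_samples=300)
        for t, pi in zip(mcmc_trees(res, aln.taxa), res["sampled_pi"]):
            assert pi == init.pi
            assert is_cube_compatible(t, pi)

    def test_acceptance_rates_strictly_between_zero_and_one(self, rng):
        T = simulate_yule(6, 6.0, rng)
        aln = simulate_alignment(T, hky_model(2.0), length=100, rng=rng)
        model = PhyloPosterior(aln)
        res = run_cube_mcmc(model, model.init_state(T, rng), 6000, rng)
        for op in ("slide", "scale", "param:kappa"):
            assert 0.0 < res["acceptance"][op] < 1.0

    def test_fit_variational_psd_covariance_and_dims(self, rng):
        d = yule_hky_design(length=100, n_taxa=6)
        truth = d.draw_truth(rng)
        tree, aln = d.simulate(truth, rng)
        post = fit_variational(aln, multiplier=400, rng=rng,
                               schedule=AnnealingSchedule(steps_per_segment=60))
        assert post.k == (6 - 1) + 2
        eig = np.linalg.eigvalsh(post.sigma)
        assert eig.min() > -1e-10
        # summary tree is the z=0 decode of the gap block
        s = post.summary_tree()
        assert sorted(s.taxa) == sorted(aln.taxa)
        assert is_cube_compatible(s, post.pi)

    def test_fit_single_topology_data_summary_matches_map(self, rng):
        """With strongly informative data the summary tree carries the MAP
        (= dominant posterior) topology."""
        T = simulate_yule(5, 2.0, rng)  # tall tree, well-resolved
        aln = simulate_alignment(T, hky_model(2.0), length=4000, rng=rng)
        post, mcmc = fit_variational(
            aln, multiplier=500, rng=rng, return_mcmc=True,
            schedule=AnnealingSchedule(steps_per_segment=80))
        counts = Counter(t.topology_key() for t in mcmc_trees(mcmc, aln.taxa))
        dominant = counts.most_common(1)[0][0]
        assert post.summary_tree().topology_key() == dominant

    def test_variational_posterior_json_roundtrip(self, rng):
        d = yule_hky_design(length=60, n_taxa=4)
        truth = d.draw_truth(rng)
        _, aln = d.simulate(truth, rng)
        post = fit_variational(aln, multiplier=200, rng=rng,
                               schedule=AnnealingSchedule(steps_per_segment=30))
        back = VariationalPosterior.from_json(post.to_json())
        np.testing.assert_allclose(back.mu, post.mu)
        np.testing.assert_allclose(back.sigma, post.sigma)
        assert back.pi == post.pi
        assert back.summary_tree().same_tree(post.summary_tree(), atol=1e-9)
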