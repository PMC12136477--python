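"""Sampler conditionals against closed-form and simulation oracles."""

import math

import numpy as np
import pytest
from scipy import stats

from softmix.sampler import (MixtureDataset, ModelState, SamplerConfig,
                             draw_leaf_values, integrated_log_likelihood,
                             log_tree_prior, propose_move, run_mcmc,
                             update_beta, update_dirichlet_mass,
                             update_sigma2, update_sigma_mu,
                             update_split_probs, update_tau, update_tree)
from softmix.soft_forest import (ForestState, SoftTree, SoftTreeNode,
                                 basis_matrix)
from softmix.synthetic_data import SimCaseSpec, gen_dataset

from conftest import random_tree


def make_forest(trees, s=None, **kw):
    M = len(s) if s is not None else 3
    return ForestState(trees=trees, split_probs=s if s is not None
                       else np.ones(M) / M, **kw)


def stump():
    return SoftTree(SoftTreeNode())


class TestLogTreePrior:
    def test_single_leaf_prior(self):
        forest = make_forest([stump()], depth_gamma=0.3, depth_beta=2.0)
        assert log_tree_prior(stump(), forest) == pytest.approx(math.log(0.7))

    def test_root_split_hand_computation(self):
        # root branch (depth 0, full [0,1] cutpoint interval, uniform s over
        # 3 vars) plus two depth-1 leaves
        tree = SoftTree(SoftTreeNode(split_index=1, cutpoint=0.4,
                                     left=SoftTreeNode(), right=SoftTreeNode()),
                        tau=0.1)
        forest = make_forest([tree], depth_gamma=0.3, depth_beta=2.0)
        expected = (math.log(0.3) + math.log(1 / 3) + math.log(1.0)
                    + 2 * math.log(1 - 0.3 * 2 ** -2.0))
        assert log_tree_prior(tree, forest) == pytest.approx(expected)

    def test_depth_penalty_prefers_shallow_topologies(self):
        # chain of two splits (depth 2) vs balanced pair at depth 1:
        # same node count, deeper one carries less prior mass
        deep = SoftTree(SoftTreeNode(
            split_index=0, cutpoint=0.5,
            left=SoftTreeNode(split_index=1, cutpoint=0.5,
                              left=SoftTreeNode(), right=SoftTreeNode()),
            right=SoftTreeNode()))
        forest = make_forest([deep], depth_gamma=0.3, depth_beta=2.0)
        lp_deep = log_tree_prior(deep, forest)
        shallow = SoftTree(SoftTreeNode(split_index=0, cutpoint=0.5,
                                        left=SoftTreeNode(),
                                        right=SoftTreeNode()))
        lp_shallow = log_tree_prior(shallow, forest)
        assert lp_deep < lp_shallow

    def test_invalid_gamma_rejected(self):
        forest = make_forest([stump()], depth_gamma=0.3)
        forest.depth_gamma = 1.5
        with pytest.raises(ValueError):
            log_tree_prior(stump(), forest)


class TestIntegratedLogLikelihood:
    @pytest.mark.parametrize("n", [15, 20, 30])
    def test_woodbury_matches_dense_cholesky(self, rng, n):
        tree = random_tree(rng, n_vars=2, p_split=0.8, max_depth=3)
        Z = rng.uniform(0, 1, size=(n, 2))
        r = rng.standard_normal(n)
        sigma2, sigma_mu = 0.4, 0.21
        ll = integrated_log_likelihood(tree, Z, r, sigma2, sigma_mu)
        Phi = basis_matrix(Z, tree)
        cov = sigma2 * np.eye(n) + sigma_mu ** 2 * Phi @ Phi.T
        dense = stats.multivariate_normal(np.zeros(n), cov).logpdf(r)
        assert ll == pytest.approx(dense, abs=1e-8)

    def test_zero_leaf_scale_collapses_to_iid_gaussian(self, rng):
        tree = random_tree(rng)
        r = rng.standard_normal(12)
        ll = integrated_log_likelihood(tree, np.zeros((12, 3)), r, 0.7, 0.0)
        assert ll == pytest.approx(
            stats.norm.logpdf(r, scale=math.sqrt(0.7)).sum())

    def test_nonpositive_variance_rejected(self):
        with pytest.raises(ValueError):
            integrated_log_likelihood(stump(), np.zeros((10, 1)),
                                      np.zeros(10), -1.0, 0.1)


class TestProposeMove:
    def test_grow_from_stump_gives_depth_one_tree(self, rng):
        s = np.ones(3) / 3
        for _ in range(10):
            res = propose_move(stump(), s, rng)
            assert res.move == "grow"
            assert res.tree.n_leaves() == 2

    def test_degenerate_split_probs_pin_the_variable(self, rng):
        s = np.array([1.0, 0.0, 0.0])
        for _ in range(20):
            res = propose_move(stump(), s, rng)
            assert res.tree.root.split_index == 0

    def test_grow_then_prune_proposal_densities_are_reciprocal(self, rng):
        # growing a stump and pruning straight back traverses the same pair
        # of states, so the two log proposal ratios must cancel
        s = np.array([0.5, 0.3, 0.2])
        grown = propose_move(stump(), s, rng)
        assert grown.move == "grow"
        j = grown.tree.root.split_index
        pruned = None
        r = np.random.default_rng(5)
        while pruned is None or pruned.move != "prune":
            pruned = propose_move(grown.tree, s, r)
        # reconstruct the analytic densities of the grow step
        lq_grow = (math.log(1.0)            # stump: grow with probability 1
                   - math.log(1)            # one leaf to choose from
                   + math.log(s[j]) - math.log(1.0))
        lq_prune_back = math.log(0.4) - math.log(1)
        assert grown.log_ratio == pytest.approx(lq_prune_back - lq_grow)
        assert pruned.log_ratio == pytest.approx(-(grown.log_ratio))
        assert pruned.tree.n_leaves() == 1


class TestConjugateUpdates:
    def test_leaf_draw_moments_match_analytic_conditional(self, rng):
        tree = SoftTree(SoftTreeNode(split_index=0, cutpoint=0.5,
                                     left=SoftTreeNode(),
                                     right=SoftTreeNode()), tau=0.2)
        n = 30
        Z = rng.uniform(0, 1, size=(n, 1))
        r = rng.standard_normal(n) + 0.8
        sigma2, sigma_mu = 0.5, 0.4
        Phi = basis_matrix(Z, tree)
        prec = Phi.T @ Phi / sigma2 + np.eye(2) / sigma_mu ** 2
        cov = np.linalg.inv(prec)
        mean = cov @ Phi.T @ r / sigma2
        draws = np.array([[lf.mu for lf in
                           draw_leaf_values(tree, Z, r, sigma2, sigma_mu,
                                            rng).leaves()]
                          for _ in range(20000)])
        se = np.sqrt(np.diag(cov) / draws.shape[0])
        np.testing.assert_allclose(draws.mean(0), mean, atol=6 * se.max())
        np.testing.assert_allclose(np.cov(draws.T), cov, atol=0.02)

    def test_leaf_draw_shrinks_to_zero_with_tiny_scale(self, rng):
        tree = stump()
        r = np.full(50, 5.0)
        out = draw_leaf_values(tree, np.zeros((50, 1)), r, 1.0, 1e-6, rng)
        assert abs(out.root.mu) < 1e-4

    def test_leaf_posterior_mean_approaches_residual_mean(self, rng):
        # single leaf, many iid residuals with mean c: conjugate shrinkage
        # limit drives the posterior mean of mu to c
        c = 1.7
        r = c + 0.01 * rng.standard_normal(5000)
        draws = [draw_leaf_values(stump(), np.zeros((5000, 1)), r, 0.25, 10.0,
                                  rng).root.mu for _ in range(200)]
        assert np.mean(draws) == pytest.approx(c, abs=0.01)

    def test_beta_moments_match_flat_prior_conditional(self, rng):
        n, d = 40, 2
        X = rng.standard_normal((n, d))
        Y = X @ np.array([1.0, -2.0]) + rng.standard_normal(n)
        data = MixtureDataset(Y=Y, Z=rng.standard_normal((n, 1)), X=X)
        fit = np.zeros(n)
        sigma2 = 0.8
        mean = np.linalg.solve(X.T @ X, X.T @ Y)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        draws = []
        for _ in range(20000):
            state = ModelState(forest=make_forest([stump()], np.ones(1)),
                               beta=np.zeros(d), sigma2=sigma2, fit=fit)
            draws.append(update_beta(state, data, rng))
        draws = np.array(draws)
        se = np.sqrt(np.diag(cov) / draws.shape[0])
        np.testing.assert_allclose(draws.mean(0), mean, atol=6 * se.max())

    def test_beta_collapses_to_ols_as_sigma2_vanishes(self, rng):
        n = 30
        X = rng.standard_normal((n, 2))
        Y = X @ np.array([2.0, 2.0]) + rng.standard_normal(n)
        data = MixtureDataset(Y=Y, Z=rng.standard_normal((n, 1)), X=X)
        state = ModelState(forest=make_forest([stump()], np.ones(1)),
                           beta=np.zeros(2), sigma2=1e-12, fit=np.zeros(n))
        beta = update_beta(state, data, rng)
        ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(beta, ols, atol=1e-4)

    def test_beta_noop_without_confounders(self, rng):
        data = MixtureDataset(Y=np.zeros(12), Z=np.zeros((12, 1)), X=None)
        state = ModelState(forest=make_forest([stump()], np.ones(1)),
                           beta=np.empty(0), sigma2=1.0, fit=np.zeros(12))
        assert update_beta(state, data, rng).size == 0

    def test_beta_rank_deficiency_is_diagnosed(self, rng):
        X = np.zeros((20, 2))
        X[:, 0] = rng.standard_normal(20)
        data = MixtureDataset(Y=np.zeros(20), Z=np.zeros((20, 1)), X=X,
                              confounder_names=["good", "allzero"])
        state = ModelState(forest=make_forest([stump()], np.ones(1)),
                           beta=np.zeros(2), sigma2=1.0, fit=np.zeros(20))
        with pytest.raises(ValueError, match="allzero"):
            update_beta(state, data, rng)

    def test_sigma2_posterior_mean_recovers_residual_variance(self, rng):
        n = 10000
        r = rng.normal(0, math.sqrt(0.5), size=n)
        data = MixtureDataset(Y=r, Z=np.zeros((n, 1)), X=None)
        state = ModelState(forest=make_forest([stump()], np.ones(1)),
                           beta=np.empty(0), sigma2=1.0, fit=np.zeros(n))
        draws = [update_sigma2(state, data, rng, ig_shape=3.0, ig_scale=0.1)
                 for _ in range(300)]
        assert np.mean(draws) == pytest.approx(0.5, abs=0.05)
        assert np.min(draws) > 0

    def test_split_prob_update_is_conjugate_dirichlet(self, rng):
        # no splits, a = M: posterior is Dirichlet(1, 1, 1)
        forest = make_forest([stump()] * 4, dirichlet_mass=3.0)
        draws = np.array([update_split_probs(forest, rng)
                          for _ in range(10000)])
        np.testing.assert_allclose(draws.mean(0), 1 / 3, atol=0.02)
        # concentrated counts dominate a small mass
        grown = SoftTree(SoftTreeNode(split_index=0, cutpoint=0.5,
                                      left=SoftTreeNode(),
                                      right=SoftTreeNode()))
        forest = make_forest([grown] * 100, dirichlet_mass=0.5)
        draws = np.array([update_split_probs(forest, rng)
                          for _ in range(2000)])
        assert draws.mean(0)[0] > 0.95


class TestBandwidthAndMass:
    def test_tau_chain_without_likelihood_samples_its_prior(self):
        # single-leaf tree: the marginal likelihood is tau-free, so the MH
        # chain must reproduce the exponential prior (mean 0.1)
        rng = np.random.default_rng(99)
        Z = np.zeros((10, 1))
        r = np.zeros(10)
        tree = stump()
        taus = []
        for i in range(8000):
            tree = update_tau(tree, Z, r, 1.0, 0.1, rng)
            if i % 10 == 0:
                taus.append(tree.tau)
        ks = stats.kstest(taus[50:], stats.expon(scale=0.1).cdf)
        assert ks.pvalue > 0.01

    def test_zero_proposal_sd_keeps_tau_fixed(self, rng):
        tree = SoftTree(SoftTreeNode(), tau=0.2)
        out = update_tau(tree, np.zeros((10, 1)), np.zeros(10), 1.0, 0.1,
                         rng, prop_sd=0.0)
        assert out.tau == 0.2

    def test_mass_prior_chain_recovers_beta_half_one(self):
        rng = np.random.default_rng(7)
        forest = make_forest([stump()], dirichlet_mass=1.0)
        us = []
        for i in range(30000):
            a = update_dirichlet_mass(forest, rng, likelihood=False)
            if i % 15 == 0:
                us.append(a / (a + 3))
        ks = stats.kstest(us[100:], stats.beta(0.5, 1).cdf)
        assert ks.pvalue > 0.01

    def test_mass_larger_under_uniform_than_concentrated_simplex(self):
        rng = np.random.default_rng(3)
        meds = []
        for s in (np.full(8, 1 / 8),
                  np.array([0.93] + [0.01] * 7)):
            forest = make_forest([stump()] * 1, s=s, dirichlet_mass=1.0)
            chain = [update_dirichlet_mass(forest, rng) for _ in range(5000)]
            meds.append(np.median(chain[500:]))
        assert meds[0] > meds[1]

    def test_zero_proposal_sd_keeps_mass_fixed(self, rng):
        forest = make_forest([stump()], dirichlet_mass=2.0)
        assert update_dirichlet_mass(forest, rng, prop_sd=0.0) == 2.0

    def test_sigma_mu_update_tracks_leaf_spread(self):
        rng = np.random.default_rng(11)
        big = rng.normal(0, 0.5, size=200)
        small = rng.normal(0, 0.01, size=200)
        sm_big = 0.05
        sm_small = 0.05
        for _ in range(2000):
            sm_big = update_sigma_mu(sm_big, big, 0.05, rng)
            sm_small = update_sigma_mu(sm_small, small, 0.05, rng)
        assert 0.4 < sm_big < 0.65
        assert sm_small < 0.03


class TestTreeUpdate:
    def test_noise_keeps_trees_near_stumps(self, rng):
        # pure-noise residuals: the depth penalty dominates and the tree
        # hovers near the prior (mean leaf count ~1.35), far below bushy
        n = 80
        data = MixtureDataset(Y=rng.standard_normal(n),
                              Z=rng.uniform(0, 1, (n, 2)), X=None)
        forest = make_forest([stump()], s=np.ones(2) / 2, sigma_mu=0.1,
                             depth_gamma=0.3, depth_beta=2.0)
        state = ModelState(forest=forest, beta=np.empty(0), sigma2=1.0,
                           fit=np.zeros(n))
        leaves = []
        for _ in range(500):
            update_tree(state, data, 0, rng)
            leaves.append(forest.trees[0].n_leaves())
        assert np.mean(leaves[100:]) < 1.8

    def test_update_refreshes_cached_fit(self, rng):
        n = 50
        data = MixtureDataset(Y=np.sin(6 * np.linspace(0, 1, n)),
                              Z=np.linspace(0, 1, n)[:, None], X=None)
        forest = make_forest([stump()], s=np.ones(1), sigma_mu=0.3,
                             depth_gamma=0.3, depth_beta=2.0)
        state = ModelState(forest=forest, beta=np.empty(0), sigma2=0.05,
                           fit=np.zeros(n))
        for _ in range(50):
            update_tree(state, data, 0, rng)
        tree = forest.trees[0]
        mu = np.array([lf.mu for lf in tree.leaves()])
        np.testing.assert_allclose(state.fit,
                                   basis_matrix(data.Z, tree) @ mu,
                                   atol=1e-10)


class TestRunMcmc:
    def test_identical_seeds_give_identical_chains(self):
        bundle = gen_dataset(SimCaseSpec(case_id=1, n=60, rng_seed=4))
        cfg = SamplerConfig(total_draws=300, burn_in=100, thin=1, rng_seed=42)
        d1 = run_mcmc(bundle.dataset, cfg)
        d2 = run_mcmc(bundle.dataset, cfg)
        np.testing.assert_array_equal(d1.sigma2, d2.sigma2)
        np.testing.assert_array_equal(d1.beta, d2.beta)
        np.testing.assert_array_equal(d1.h_train, d2.h_train)
        np.testing.assert_array_equal(d1.split_probs, d2.split_probs)
        for a, b in zip(d1.snapshots[-1], d2.snapshots[-1]):
            np.testing.assert_array_equal(a, b)

    def test_inactive_exposure_is_not_selected(self):
        # with signal present, the Dirichlet sparsity concentrates the split
        # simplex on the active exposures and the inactive one falls below
        # the 0.5 selection threshold
        from softmix.summaries import compute_pip
        ok = 0
        for seed in range(3):
            bundle = gen_dataset(SimCaseSpec(case_id=1, n=100,
                                             rng_seed=seed + 30))
            d = run_mcmc(bundle.dataset,
                         SamplerConfig(total_draws=1500, thin=3,
                                       rng_seed=seed + 50))
            pip = compute_pip(d).pip
            if pip[2] < 0.5 and pip[0] > 0.5 and pip[1] > 0.5:
                ok += 1
        assert ok >= 2

    def test_step_function_drives_bandwidth_below_data_scale(self):
        rng = np.random.default_rng(0)
        n = 150
        z = rng.uniform(0, 1, n)
        y = (z > 0.5).astype(float) + rng.normal(0, 0.1, n)
        data = MixtureDataset(Y=y, Z=z[:, None], X=None)
        d = run_mcmc(data, SamplerConfig(n_trees=10, total_draws=800,
                                         thin=2, rng_seed=9))
        taus = np.concatenate([snap[6] for snap in d.snapshots[-100:]])
        assert np.median(taus) < 0.5

    def test_case1_large_sample_recovers_generating_parameters(self):
        # beta = (2, 2) and sigma2 = 0.5 within 0.1 at n = 1000
        bundle = gen_dataset(SimCaseSpec(case_id=1, n=1000, rng_seed=8))
        d = run_mcmc(bundle.dataset,
                     SamplerConfig(total_draws=2500, thin=5, rng_seed=15))
        np.testing.assert_allclose(d.beta.mean(0), [2.0, 2.0], atol=0.1)
        assert d.sigma2.mean() == pytest.approx(0.5, abs=0.1)
        # sampler health is logged, not asserted: structure acceptance drops
        # with n as the marginal likelihood sharpens
        assert 0.0 < d.diagnostics["accept_rate"] < 0.9

    def test_posterior_draws_json_roundtrip(self):
        from softmix.sampler import PosteriorDraws
        bundle = gen_dataset(SimCaseSpec(case_id=1, n=60, rng_seed=4))
        d = run_mcmc(bundle.dataset,
                     SamplerConfig(total_draws=240, burn_in=120, rng_seed=1))
        back = PosteriorDraws.from_json(d.to_json())
        np.testing.assert_allclose(back.sigma2, d.sigma2)
        np.testing.assert_allclose(back.h_train, d.h_train)
        for a, b in zip(back.snapshots[3], d.snapshots[3]):
            np.testing.assert_allclose(a, b)
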