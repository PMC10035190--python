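"""Adaptive-Metropolis/delayed-rejection kernel and the Gibbs driver."""

import numpy as np
import pytest
from scipy import stats

import kinbayes as kb
from kinbayes.sampler import _RunningCovariance


class TestConditionalProposalVariance:
    def test_diagonal_covariance_gives_diagonal_entry(self):
        C = np.diag([2.0, 3.0, 4.0])
        for i in range(3):
            assert kb.conditional_proposal_variance(C, i) == pytest.approx(C[i, i])

    def test_two_by_two_hand_example(self):
        C = np.array([[2.0, 1.0], [1.0, 2.0]])
        assert kb.conditional_proposal_variance(C, 0) == pytest.approx(1.5)
        assert kb.conditional_proposal_variance(C, 1) == pytest.approx(1.5)

    def test_one_dimensional_case(self):
        assert kb.conditional_proposal_variance(np.array([[0.7]]), 0) == pytest.approx(0.7)

    def test_equals_inverse_diagonal_identity(self):
        """Schur complement == 1/(C^-1)_ii, the identity the sweep engine uses."""
        rng = np.random.default_rng(3)
        A = rng.normal(size=(5, 5))
        C = A @ A.T + 5 * np.eye(5)
        Cinv = np.linalg.inv(C)
        for i in range(5):
            assert kb.conditional_proposal_variance(C, i) == pytest.approx(
                1.0 / Cinv[i, i], rel=1e-10
            )


class TestAdaptationCovariance:
    def test_pre_adaptation_returns_initial_covariance(self):
        C0 = np.diag([0.2, 0.5])
        cfg = kb.SamplerConfig(n_iter=100, burn_in=10, l0=20, dr_onset=30, C0=C0)
        hist = np.zeros((5, 2))
        assert np.array_equal(kb.update_adaptation_covariance(hist, 5, cfg), C0)

    def test_constant_history_gives_ridge_only(self):
        cfg = kb.SamplerConfig(n_iter=100, burn_in=10, l0=5, dr_onset=30, C0=np.eye(2))
        hist = np.ones((20, 2))
        C = kb.update_adaptation_covariance(hist, 20, cfg)
        s_d = 2.4**2 / 2
        assert np.allclose(C, s_d * cfg.epsilon * np.eye(2))

    def test_matches_sample_covariance_oracle(self):
        rng = np.random.default_rng(11)
        hist = rng.normal(size=(10, 2))
        cfg = kb.SamplerConfig(n_iter=100, burn_in=10, l0=5, dr_onset=30, C0=np.eye(2))
        C = kb.update_adaptation_covariance(hist, 10, cfg)
        s_d = 2.4**2 / 2
        expected = s_d * np.cov(hist, rowvar=False) + s_d * cfg.epsilon * np.eye(2)
        assert np.allclose(C, expected)

    def test_insufficient_history_raises(self):
        cfg = kb.SamplerConfig(n_iter=100, burn_in=10, l0=5, dr_onset=30, C0=np.eye(2))
        with pytest.raises(kb.SamplerError):
            kb.update_adaptation_covariance(np.ones((1, 2)), 6, cfg)

    def test_running_covariance_equals_batch(self):
        rng = np.random.default_rng(2)
        hist = rng.normal(size=(50, 3))
        rc = _RunningCovariance(3)
        for row in hist:
            rc.update(row)
        assert np.allclose(rc.cov(), np.cov(hist, rowvar=False), rtol=1e-10)


class TestDRMetropolisUpdate:
    def test_identical_target_value_accepts_at_stage_one(self):
        rng = np.random.default_rng(0)
        val, stage = kb.dr_metropolis_update(
            0, np.array([0.0]), lambda x: 0.0, D_i=1.0, gamma=0.25, rng=rng
        )
        assert stage == 1

    def test_stage_two_attempted_after_minus_inf_stage_one(self):
        """A -inf stage-1 target forces rejection and triggers the second stage."""
        evals = []

        def log_target(x):
            evals.append(float(x[0]))
            return -np.inf if x[0] != 0.0 else 0.0

        rng = np.random.default_rng(1)
        val, stage = kb.dr_metropolis_update(
            0, np.array([0.0]), log_target, D_i=1.0, gamma=0.25, rng=rng
        )
        assert stage == 0 and val == 0.0
        assert len(evals) == 3  # current + stage-1 + stage-2 proposals

    def test_nan_target_is_an_error_distinct_from_minus_inf(self):
        rng = np.random.default_rng(2)
        with pytest.raises(kb.SamplerError):
            kb.dr_metropolis_update(
                0, np.array([0.0]), lambda x: np.nan, D_i=1.0, gamma=0.25, rng=rng
            )

    def test_standard_normal_target_moments(self):
        """10^5 composite updates of a 1-D N(0,1) target recover its moments."""
        cfg = kb.SamplerConfig(
            n_iter=100_000, burn_in=5_000, l0=500, dr_onset=1_000, C0=np.eye(1), seed=5
        )
        draws, acc = kb.sample_mwg(lambda x: -0.5 * float(x @ x), np.zeros(1), cfg)
        post = draws[cfg.burn_in :, 0]
        assert abs(post.mean()) < 0.02
        assert post.var() == pytest.approx(1.0, rel=0.03)
        s1, s2, total = acc["x0"]
        assert s1 + s2 <= total and total == cfg.n_iter


class TestGibbsSampler:
    def test_identical_seed_gives_bit_identical_chains(
        self, decay2_model, decay2_prior, decay2_data, small_config
    ):
        hyper = kb.estimate_shrinkage_hyperparams(decay2_data)
        a = kb.run_gibbs_sampler(decay2_model, decay2_data, decay2_prior, hyper, small_config)
        b = kb.run_gibbs_sampler(decay2_model, decay2_data, decay2_prior, hyper, small_config)
        assert np.array_equal(a.beta_draws, b.beta_draws)
        assert np.array_equal(a.sigma2_draws, b.sigma2_draws)

    def test_chain_respects_constraints_and_accounting(
        self, decay2_model, decay2_prior, decay2_data, small_config
    ):
        hyper = kb.estimate_shrinkage_hyperparams(decay2_data)
        chain = kb.run_gibbs_sampler(
            decay2_model, decay2_data, decay2_prior, hyper, small_config
        )
        assert np.all(chain.beta_draws >= decay2_prior.zeta_l)
        assert np.all(chain.beta_draws <= decay2_prior.zeta_u)
        assert np.all(chain.sigma2_draws > 0)
        assert np.all(np.isfinite(chain.log_posterior_trace))
        for s1, s2, total in chain.acceptance.values():
            assert s1 + s2 <= total and total == small_config.n_iter

    def test_sigma2_marginal_matches_conjugate_oracle(self):
        """With a constant-mean model the sigma^2 marginal is exactly the
        analytic inverse-gamma conditional, whatever the beta chain does."""
        model = kb.KineticModelSpec(
            state_names=["a", "b"],
            initial_state=np.array([2.0, 1.0]),
            rhs=lambda mu, k, t: np.zeros_like(mu),
            parameter_names=["k_idle"],
        )
        rng = np.random.default_rng(8)
        times = np.array([1.0, 2.0, 3.0])
        y = np.exp(np.log([2.0, 1.0])[None, None, :] + 0.3 * rng.standard_normal((3, 4, 2)))
        data = kb.TimeSeriesDataset(times=times, abundances=y, isotopomers=["a", "b"])
        prior = kb.BetaPrior(np.zeros(1), np.eye(1), np.full(1, -3), np.full(1, 3))
        hyper = kb.estimate_shrinkage_hyperparams(data)
        cfg = kb.SamplerConfig(n_iter=4000, burn_in=500, l0=100, dr_onset=200, seed=3)
        chain = kb.run_gibbs_sampler(model, data, prior, hyper, cfg)
        from kinbayes.model import residual_sums
        from kinbayes.priors import sigma2_conditional_params

        ss = residual_sums(model, np.zeros(1), data)
        for i in range(2):
            shape, scale = sigma2_conditional_params(float(ss[i]), hyper, data.m, data.T)
            ks = stats.kstest(
                chain.posterior_sigma2[:, i], stats.invgamma(a=shape, scale=scale).cdf
            )
            assert ks.pvalue > 0.01

    def test_adaptation_off_agrees_with_adaptive_on_gaussian_target(self):
        """With l0 = n_iter the kernel is plain component-wise MH + DR; both
        variants must agree on a Gaussian target within Monte-Carlo error."""
        target = lambda x: -0.5 * float(x @ x)
        n = 40_000
        adaptive = kb.SamplerConfig(
            n_iter=n, burn_in=4000, l0=500, dr_onset=800, C0=np.eye(2), seed=21
        )
        plain = kb.SamplerConfig(
            n_iter=n, burn_in=4000, l0=n - 1, dr_onset=800, C0=np.eye(2), seed=22
        )
        da, _ = kb.sample_mwg(target, np.zeros(2), adaptive)
        dp, _ = kb.sample_mwg(target, np.zeros(2), plain)
        for d in (da, dp):
            post = d[4000:]
            assert np.all(np.abs(post.mean(axis=0)) < 0.05)
            assert np.allclose(post.var(axis=0), 1.0, rtol=0.08)

    def test_initial_beta_outside_bounds_rejected(
        self, decay2_model, decay2_prior, decay2_data, small_config
    ):
        hyper = kb.estimate_shrinkage_hyperparams(decay2_data)
        with pytest.raises(kb.SamplerError):
            kb.run_gibbs_sampler(
                decay2_model,
                decay2_data,
                decay2_prior,
                hyper,
                small_config,
                initial_beta=decay2_prior.zeta_u + 1.0,
            )

    def test_invalid_config_rejected(self):
        with pytest.raises(kb.SamplerError):
            kb.SamplerConfig(n_iter=100, burn_in=10, l0=100, dr_onset=10)  # l0 >= n_iter
        with pytest.raises(kb.SamplerError):
            kb.SamplerConfig(n_iter=100, burn_in=10, l0=10, dr_onset=10, gamma=-1.0)
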