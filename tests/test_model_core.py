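"""Kinetic model core: trajectory integration, likelihood, posterior, fluxes."""

import math

import numpy as np
import pytest

import kinbayes as kb
from kinbayes.model import log_likelihood_from_ss, residual_sums

from conftest import make_dataset


def constant_model(n_state=2, initial=(2.0, 3.0)):
    """A network whose states never move (rhs identically zero)."""
    return kb.KineticModelSpec(
        state_names=[f"s{i}" for i in range(n_state)],
        initial_state=np.asarray(initial, float),
        rhs=lambda mu, k, t: np.zeros_like(mu),
        parameter_names=["k_dummy"],
    )


def single_decay_model(mu0=1.0):
    """One-state first-order decay d mu/dt = -k mu."""
    return kb.KineticModelSpec.from_reactions(
        state_names=["A"],
        initial_state=[mu0],
        reactions=[kb.Reaction("k", ("A",), ())],
    )


class TestSolveMeanTrajectories:
    def test_zero_rhs_returns_initial_state_everywhere(self):
        model = constant_model()
        times = np.array([0.5, 1.0, 4.0])
        mu = kb.solve_mean_trajectories(model, np.array([0.3]), times)
        assert np.allclose(mu, np.tile(model.initial_state, (3, 1)), atol=1e-9)

    def test_first_order_decay_closed_form(self):
        mu = kb.solve_mean_trajectories(single_decay_model(), np.array([0.0]), np.array([1.0]))
        assert mu[0, 0] == pytest.approx(math.exp(-1.0), abs=1e-5)

    def test_two_pool_conversion_closed_form(self):
        model = kb.KineticModelSpec.from_reactions(
            ["A", "B"], [1.0, 0.0], [kb.Reaction("k", ("A",), ("B",))]
        )
        mu = kb.solve_mean_trajectories(model, np.array([np.log(0.5)]), np.array([2.0]))
        assert mu[0, 0] == pytest.approx(math.exp(-1.0), abs=1e-5)
        assert mu[0, 1] == pytest.approx(1.0 - math.exp(-1.0), abs=1e-5)

    def test_tightened_tolerances_agree_within_loose_tolerance(self, decay2_model, decay2_truth):
        times = kb.DEFAULT_TIMES
        loose = kb.solve_mean_trajectories(decay2_model, decay2_truth, times)
        tight = kb.solve_mean_trajectories(
            decay2_model, decay2_truth, times, rtol=1e-7, atol=1e-10
        )
        assert np.max(np.abs(loose - tight)) < 1e-6 * np.max(loose) + 1e-9

    def test_time_zero_returns_initial(self, decay2_model, decay2_truth):
        mu = kb.solve_mean_trajectories(decay2_model, decay2_truth, np.array([0.0, 1.0]))
        assert np.allclose(mu[0], decay2_model.initial_state)

    def test_invalid_inputs_raise(self, decay2_model):
        with pytest.raises(kb.ModelSpecError):
            kb.solve_mean_trajectories(decay2_model, np.array([np.nan, 0.0]), np.array([1.0]))
        with pytest.raises(kb.ModelSpecError):
            kb.solve_mean_trajectories(decay2_model, np.zeros(2), np.array([2.0, 1.0]))

    def test_mass_conservation_in_closed_network(self, pool3_model):
        beta = kb.EXEMPLAR_BETA_TRUE["pool3_mini"]
        mu = kb.solve_mean_trajectories(pool3_model, beta, kb.DEFAULT_TIMES)
        total = mu.sum(axis=1)
        assert np.allclose(total, pool3_model.initial_state.sum(), rtol=1e-6)


class TestDatasetValidation:
    def test_shape_and_positivity_rules(self):
        with pytest.raises(kb.DataError):
            make_dataset([1.0, 2.0], np.zeros((2, 2, 1)) - 1.0, ["a"])
        with pytest.raises(kb.DataError):
            make_dataset([2.0, 1.0], np.ones((2, 2, 1)), ["a"])  # times not increasing
        with pytest.raises(kb.DataError):
            make_dataset([1.0], np.ones((1, 2, 1)), ["a"])  # T < 2

    def test_valid_dataset_exposes_dimensions(self, decay2_data):
        assert (decay2_data.T, decay2_data.m, decay2_data.n) == (6, 3, 2)
        assert np.allclose(decay2_data.log_abundances, np.log(decay2_data.abundances))


class TestLogLikelihood:
    def test_zero_noise_and_unit_variance_gives_zero(self, decay2_model, decay2_truth):
        data = kb.simulate_dataset(
            decay2_model,
            decay2_truth,
            kb.NoiseSpec(sigma2=0.0),
            kb.DEFAULT_TIMES,
            m=2,
            seed=0,
        )
        val = kb.log_likelihood(decay2_truth, np.ones(2), data, decay2_model)
        assert val == pytest.approx(0.0, abs=1e-8)

    def test_hand_evaluated_single_cell(self):
        # one isotopomer, one replicate, one time, sigma^2 = 1, log-residual 2
        assert log_likelihood_from_ss(np.array([4.0]), np.array([1.0]), m=1, T=1) == -2.0

    def test_matches_brute_force_triple_sum(self, decay2_model, decay2_truth, decay2_data):
        rng = np.random.default_rng(5)
        sigma2 = rng.uniform(0.05, 0.4, size=2)
        val = kb.log_likelihood(decay2_truth, sigma2, decay2_data, decay2_model)
        # independent direct evaluation of the stated formula
        mu = kb.solve_mean_trajectories(decay2_model, decay2_truth, decay2_data.times)
        mu = mu[:, decay2_model.observed_indices]
        total = 0.0
        for i in range(decay2_data.n):
            total -= (decay2_data.m * decay2_data.T / 2) * math.log(sigma2[i])
            for t in range(decay2_data.T):
                for j in range(decay2_data.m):
                    r = math.log(decay2_data.abundances[t, j, i]) - math.log(mu[t, i])
                    total -= 0.5 * r * r / sigma2[i]
        assert val == pytest.approx(total, rel=1e-12)

    def test_zero_mean_cell_is_domain_error(self):
        # a state with no inflow and zero initial value stays exactly zero
        model = kb.KineticModelSpec.from_reactions(
            ["A", "dead"], [1.0, 0.0], [kb.Reaction("k", ("A",), ())]
        )
        data = make_dataset([1.0, 2.0], np.full((2, 2, 2), 0.5), ["A", "dead"])
        with pytest.raises(kb.DataError):
            kb.log_likelihood(np.array([0.0]), np.ones(2), data, model)

    def test_shape_mismatch_raises(self, decay2_model, decay2_truth, decay2_data):
        with pytest.raises(kb.DataError):
            kb.log_likelihood(decay2_truth, np.ones(3), decay2_data, decay2_model)


class TestLogPosterior:
    def test_out_of_bounds_beta_is_minus_inf(self, decay2_model, decay2_prior, decay2_data):
        hyper = kb.estimate_shrinkage_hyperparams(decay2_data)
        beta = decay2_prior.zeta_u + 1.0
        assert kb.log_posterior(
            beta, np.ones(2), decay2_data, decay2_model, decay2_prior, hyper
        ) == -np.inf

    def test_matches_term_by_term_oracle(self, decay2_model, decay2_prior, decay2_data):
        hyper = kb.estimate_shrinkage_hyperparams(decay2_data)
        rng = np.random.default_rng(9)
        beta = decay2_prior.xi + rng.normal(0, 0.2, size=2)
        sigma2 = rng.uniform(0.05, 0.3, size=2)
        lp = kb.log_posterior(beta, sigma2, decay2_data, decay2_model, decay2_prior, hyper)
        expected = (
            kb.log_likelihood(beta, sigma2, decay2_data, decay2_model)
            + kb.log_prior_beta(beta, decay2_prior)
            + kb.log_prior_sigma2(sigma2, hyper)
        )
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_posterior_minus_likelihood_is_data_free(
        self, decay2_model, decay2_prior, decay2_truth
    ):
        """The prior contribution must not depend on which dataset is used."""
        hyper = kb.ShrinkageHyperparams(4.0, 6.0)
        sigma2 = np.array([0.1, 0.2])
        gaps = []
        for seed in (1, 2):
            data = kb.simulate_dataset(
                decay2_model, decay2_truth, kb.NoiseSpec(), kb.DEFAULT_TIMES, 3, seed=seed
            )
            gaps.append(
                kb.log_posterior(decay2_truth, sigma2, data, decay2_model, decay2_prior, hyper)
                - kb.log_likelihood(decay2_truth, sigma2, data, decay2_model)
            )
        assert gaps[0] == pytest.approx(gaps[1], rel=1e-12)


class TestFluxTrajectory:
    @staticmethod
    def _chain(draws):
        draws = np.asarray(draws, float)
        L = draws.shape[0]
        return kb.PosteriorChain(
            beta_draws=draws,
            sigma2_draws=np.ones((L, 1)),
            log_posterior_trace=np.zeros(L),
            acceptance={},
            burn_in=0,
            parameter_names=["k"],
        )

    def test_degenerate_chain_has_zero_width_band(self):
        model = single_decay_model()
        chain = self._chain(np.zeros((50, 1)))
        traj = kb.compute_flux_trajectory(model, chain, "k:A->0", np.array([0.0, 1.0]))
        assert np.allclose(traj.lower, traj.mean)
        assert np.allclose(traj.upper, traj.mean)

    def test_single_draw_decay_flux_at_time_zero(self):
        # flux k * mu(0) = 1 * 1 for k = 1, mu0 = 1
        model = single_decay_model(mu0=1.0)
        chain = self._chain(np.zeros((1, 1)))
        traj = kb.compute_flux_trajectory(model, chain, "k:A->0", np.array([0.0, 1.0]))
        assert traj.mean[0] == pytest.approx(1.0, abs=1e-6)
        assert traj.mean[1] == pytest.approx(math.exp(-1.0), abs=1e-5)

    def test_band_brackets_mean_pointwise(self, decay2_model):
        rng = np.random.default_rng(3)
        draws = kb.EXEMPLAR_BETA_TRUE["decay2"] + rng.normal(0, 0.1, size=(40, 2))
        chain = kb.PosteriorChain(
            beta_draws=draws,
            sigma2_draws=np.ones((40, 2)),
            log_posterior_trace=np.zeros(40),
            acceptance={},
            burn_in=0,
            parameter_names=decay2_model.parameter_names,
        )
        name = decay2_model.reactions[0].label()
        traj = kb.compute_flux_trajectory(model=decay2_model, chain=chain, flux_name=name,
                                          time_grid=kb.DEFAULT_TIMES)
        assert np.all(traj.lower <= traj.mean) and np.all(traj.mean <= traj.upper)

    def test_unknown_flux_name_raises(self, decay2_model):
        chain = self._chain(np.zeros((5, 1)))
        with pytest.raises(KeyError):
            kb.compute_flux_trajectory(decay2_model, chain, "nope", np.array([1.0]))
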