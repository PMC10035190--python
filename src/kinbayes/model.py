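"""Kinetic ODE model core.

Represents an isotopomer reaction network, integrates its mean trajectories,
and evaluates the log-likelihood and log-posterior of the hierarchical model

    log y_tji = log mu_ti + delta_tji,   delta_tji ~ N(0, sigma_i^2),
    d mu / dt = f(mu; exp(beta), t),

where ``beta`` are log rate constants and the multiplicative log-normal error
has one variance per isotopomer.  The likelihood omits the constant
-(n m T / 2) log 2*pi throughout; all Metropolis ratios and credible values
are invariant to this convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Callable, Sequence

import numpy as np
from scipy.integrate import odeint

from .exceptions import DataError, IntegrationError, ModelSpecError
from .inference import FluxTrajectory

if TYPE_CHECKING:  # pragma: no cover
    from .priors import BetaPrior, ShrinkageHyperparams
    from .sampler import PosteriorChain

DEFAULT_RTOL = 1e-6
DEFAULT_ATOL = 1e-9
# LSODA routinely undershoots zero by a few x atol on decaying states; states
# negative by less than this are clipped to 0, anything worse is an error.
_NEG_TOL = 100 * DEFAULT_ATOL
# Observed cells with mean abundance below this are a domain error (the log
# likelihood needs log mu); flooring instead would bias low-abundance species.
_MU_FLOOR = 1e-300


@dataclass(frozen=True)
class Reaction:
    """One mass-action reaction: rate = k[parameter] * prod(mu[reactants]).

    Several reactions may share one rate constant (e.g. a labeled and an
    unlabeled version of the same enzymatic step).
    """

    parameter: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    name: str | None = None

    def label(self) -> str:
        if self.name:
            return self.name
        lhs = "+".join(self.reactants) if self.reactants else "0"
        rhs = "+".join(self.products) if self.products else "0"
        return f"{self.parameter}:{lhs}->{rhs}"


@dataclass
class KineticModelSpec:
    """A kinetic ODE network with named states, parameters and fluxes.

    ``rhs(mu, k, t)`` returns d mu/dt given the state vector, the rate
    constants ``k = exp(beta)`` and time.  ``flux_definitions`` map a flux
    name to a callable ``(mu, k, t) -> float`` (concentration/time).
    """

    state_names: list[str]
    initial_state: np.ndarray
    rhs: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    parameter_names: list[str]
    observed_indices: list[int] | None = None
    flux_definitions: dict[str, Callable[[np.ndarray, np.ndarray, float], float]] = field(
        default_factory=dict
    )
    reactions: list[Reaction] | None = None

    def __post_init__(self) -> None:
        self.initial_state = np.asarray(self.initial_state, dtype=float)
        n_state = len(self.state_names)
        if self.initial_state.shape != (n_state,):
            raise ModelSpecError(
                f"initial_state has shape {self.initial_state.shape}, expected ({n_state},)"
            )
        if np.any(self.initial_state < 0):
            raise ModelSpecError("initial_state must be nonnegative")
        if len(set(self.parameter_names)) != len(self.parameter_names):
            raise ModelSpecError("parameter_names must be unique")
        if len(set(self.state_names)) != n_state:
            raise ModelSpecError("state_names must be unique")
        if self.observed_indices is None:
            self.observed_indices = list(range(n_state))
        obs = list(self.observed_indices)
        if len(set(obs)) != len(obs):
            raise ModelSpecError("observed_indices must be unique")
        if obs and (min(obs) < 0 or max(obs) >= n_state):
            raise ModelSpecError("observed_indices out of range")
        self.observed_indices = obs
        out = np.asarray(
            self.rhs(self.initial_state.astype(float), np.ones(len(self.parameter_names)), 0.0),
            dtype=float,
        )
        if out.shape != (n_state,):
            raise ModelSpecError("rhs output length must equal the number of states")

    @property
    def n_state(self) -> int:
        return len(self.state_names)

    @property
    def n_observed(self) -> int:
        return len(self.observed_indices)

    @property
    def d(self) -> int:
        return len(self.parameter_names)

    @property
    def observed_names(self) -> list[str]:
        return [self.state_names[i] for i in self.observed_indices]

    @classmethod
    def from_reactions(
        cls,
        state_names: Sequence[str],
        initial_state: Sequence[float],
        reactions: Sequence[Reaction],
        parameter_names: Sequence[str] | None = None,
        observed: Sequence[str] | None = None,
    ) -> "KineticModelSpec":
        """Build a mass-action network from a declarative reaction list.

        Products may be empty (efflux to an unmodeled sink).  A per-reaction
        flux is registered under the reaction's label.
        """
        state_names = list(state_names)
        sidx = {s: i for i, s in enumerate(state_names)}
        if parameter_names is None:
            seen: list[str] = []
            for r in reactions:
                if r.parameter not in seen:
                    seen.append(r.parameter)
            parameter_names = seen
        pidx = {p: i for i, p in enumerate(parameter_names)}
        n_state, n_rxn = len(state_names), len(reactions)
        stoich = np.zeros((n_state, n_rxn))
        react_idx: list[np.ndarray] = []
        param_idx = np.zeros(n_rxn, dtype=int)
        for j, r in enumerate(reactions):
            for s in r.reactants:
                stoich[sidx[s], j] -= 1.0
            for s in r.products:
                stoich[sidx[s], j] += 1.0
            react_idx.append(np.array([sidx[s] for s in r.reactants], dtype=int))
            if r.parameter not in pidx:
                raise ModelSpecError(f"unknown parameter {r.parameter!r} in reaction")
            param_idx[j] = pidx[r.parameter]

        # Pad reactant index lists to a rectangle pointing at a virtual state
        # held at 1.0, so all rate monomials evaluate in one vector product.
        # The scratch buffer keeps the integrator's inner loop allocation-free.
        order = max((len(ri) for ri in react_idx), default=0)
        react_mat = np.full((n_rxn, max(order, 1)), n_state, dtype=int)
        for j, ri in enumerate(react_idx):
            react_mat[j, : ri.size] = ri
        buf = np.ones(n_state + 1)

        if order <= 1:
            rvec = react_mat[:, 0]

            def rhs(mu: np.ndarray, k: np.ndarray, t: float) -> np.ndarray:
                buf[:n_state] = mu
                return stoich @ (k[param_idx] * buf[rvec])

        else:

            def rhs(mu: np.ndarray, k: np.ndarray, t: float) -> np.ndarray:
                buf[:n_state] = mu
                return stoich @ (k[param_idx] * buf[react_mat].prod(axis=1))

        def make_flux(j: int) -> Callable[[np.ndarray, np.ndarray, float], float]:
            ri, pj = react_idx[j], param_idx[j]
            return lambda mu, k, t: float(k[pj] * np.prod(mu[ri]))

        fluxes = {r.label(): make_flux(j) for j, r in enumerate(reactions)}
        obs_idx = None if observed is None else [sidx[s] for s in observed]
        return cls(
            state_names=state_names,
            initial_state=np.asarray(initial_state, dtype=float),
            rhs=rhs,
            parameter_names=list(parameter_names),
            observed_indices=obs_idx,
            flux_definitions=fluxes,
            reactions=list(reactions),
        )


@dataclass
class TimeSeriesDataset:
    """Replicated isotopomer abundance time courses on a complete T x m x n grid.

    ``abundances[t, j, i]`` is the measured concentration of isotopomer ``i``
    in replicate ``j`` at ``times[t]``; all values strictly positive so the
    log-scale error model is well defined.
    """

    times: np.ndarray
    abundances: np.ndarray
    isotopomers: list[str]

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.times.ndim != 1 or np.any(np.diff(self.times) <= 0):
            raise DataError("times must be strictly increasing")
        if np.any(self.times <= 0):
            raise DataError("observation times must be > 0")
        if self.abundances.ndim != 3:
            raise DataError("abundances must be a (time, replicate, isotopomer) array")
        T, m, n = self.abundances.shape
        if T != len(self.times):
            raise DataError("abundance grid does not match times")
        if n != len(self.isotopomers):
            raise DataError("abundance grid does not match isotopomer ids")
        if T < 2 or m < 2:
            raise DataError("need T >= 2 time points and m >= 2 replicates")
        if not np.all(np.isfinite(self.abundances)) or np.any(self.abundances <= 0):
            raise DataError("all abundances must be finite and strictly positive")
        self._log = np.log(self.abundances)

    @property
    def T(self) -> int:
        return self.abundances.shape[0]

    @property
    def m(self) -> int:
        return self.abundances.shape[1]

    @property
    def n(self) -> int:
        return self.abundances.shape[2]

    @property
    def log_abundances(self) -> np.ndarray:
        return self._log


def solve_mean_trajectories(
    model: KineticModelSpec,
    beta: np.ndarray,
    times: np.ndarray,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> np.ndarray:
    """Integrate the network from t=0 and return mean states at ``times``.

    Returns a (T, n_state) array.  Uses a stiff-capable adaptive solver
    (LSODA); rows are nonnegative up to solver tolerance (tiny negative
    excursions are clipped, larger ones raise :class:`ModelSpecError`).
    """
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (model.d,):
        raise ModelSpecError(f"beta has shape {beta.shape}, expected ({model.d},)")
    if not np.all(np.isfinite(beta)):
        raise ModelSpecError("beta must be finite")
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or times.size == 0 or np.any(np.diff(times) <= 0):
        raise ModelSpecError("times must be a nonempty strictly increasing vector")
    if times[0] < 0:
        raise ModelSpecError("times must be >= 0")
    k = np.exp(beta)
    if times[-1] == 0.0:
        return np.tile(model.initial_state, (times.size, 1))
    prepend = times[0] > 0.0
    t_grid = np.concatenate([[0.0], times]) if prepend else times
    with np.errstate(over="ignore", invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lsoda prints its own step-failure warnings
        y, info = odeint(
            lambda mu_t, t: model.rhs(mu_t, k, t),
            model.initial_state,
            t_grid,
            rtol=rtol,
            atol=atol,
            full_output=True,
        )
    if info["message"] != "Integration successful." or not np.all(np.isfinite(y)):
        t_fail = float(np.atleast_1d(info.get("tcur", [0.0]))[-1])
        raise IntegrationError(
            f"ODE integration failed near t={t_fail:g}: {info['message']}", t_fail
        )
    mu = y[1:].copy() if prepend else y.copy()
    if np.any(mu < -_NEG_TOL):
        worst = float(mu.min())
        raise ModelSpecError(
            f"state trajectory negative beyond solver tolerance (min {worst:g}); "
            "the network is misspecified for these rate constants"
        )
    np.clip(mu, 0.0, None, out=mu)
    return mu


def residual_sums(
    model: KineticModelSpec, beta: np.ndarray, data: TimeSeriesDataset
) -> np.ndarray:
    """Per-isotopomer residual sum of squares sum_tj (log y_tji - log mu_ti)^2."""
    mu = solve_mean_trajectories(model, beta, data.times)[:, model.observed_indices]
    if mu.shape[1] != data.n:
        raise DataError("dataset isotopomer count does not match model observed states")
    if np.any(mu < _MU_FLOOR):
        raise DataError("mean trajectory is zero (or denormal) at an observed cell")
    r = data.log_abundances - np.log(mu)[:, None, :]
    return np.einsum("tji,tji->i", r, r)


def log_likelihood_from_ss(
    residual_ss: np.ndarray, sigma2: np.ndarray, m: int, T: int
) -> float:
    """Gaussian log-likelihood (2*pi constant omitted) from residual sums."""
    sigma2 = np.asarray(sigma2, dtype=float)
    return float(-(m * T / 2.0) * np.sum(np.log(sigma2)) - 0.5 * np.sum(residual_ss / sigma2))


def log_likelihood(
    beta: np.ndarray,
    sigma2: np.ndarray,
    data: TimeSeriesDataset,
    model: KineticModelSpec,
) -> float:
    """Log-likelihood of the multiplicative log-normal error model.

    -(mT/2) sum_i log sigma_i^2 - 1/2 sum_tji (log y_tji - log mu_ti)^2 / sigma_i^2.
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if sigma2.shape != (data.n,):
        raise DataError(f"sigma2 has shape {sigma2.shape}, expected ({data.n},)")
    if np.any(sigma2 <= 0):
        raise DataError("sigma2 must be strictly positive")
    ss = residual_sums(model, beta, data)
    return log_likelihood_from_ss(ss, sigma2, data.m, data.T)


def log_posterior(
    beta: np.ndarray,
    sigma2: np.ndarray,
    data: TimeSeriesDataset,
    model: KineticModelSpec,
    prior: "BetaPrior",
    hyper: "ShrinkageHyperparams",
) -> float:
    """Joint log-posterior up to one additive constant.

    log-likelihood + truncated-MVN log-prior of beta + inverse-gamma log-prior
    of each sigma_i^2; -inf when beta violates the truncation box.
    """
    from .priors import log_prior_beta, log_prior_sigma2

    lp_beta = log_prior_beta(beta, prior)
    if not np.isfinite(lp_beta):
        return -np.inf
    return lp_beta + log_likelihood(beta, sigma2, data, model) + log_prior_sigma2(sigma2, hyper)


def compute_flux_trajectory(
    model: KineticModelSpec,
    chain: "PosteriorChain",
    flux_name: str,
    time_grid: np.ndarray,
    level: float = 0.95,
) -> FluxTrajectory:
    """Posterior mean and central credible band of a named flux over time.

    Integrates the network at every retained posterior draw of beta and
    evaluates the flux pointwise; the band is the central ``level`` interval.
    """
    if flux_name not in model.flux_definitions:
        raise KeyError(f"unknown flux {flux_name!r}; known: {sorted(model.flux_definitions)}")
    flux = model.flux_definitions[flux_name]
    draws = np.asarray(chain.posterior_beta, dtype=float)
    if draws.size == 0:
        raise DataError("posterior chain is empty")
    time_grid = np.asarray(time_grid, dtype=float)
    unique, inv = np.unique(draws, axis=0, return_inverse=True)
    vals_u = np.empty((unique.shape[0], time_grid.size))
    for r, b in enumerate(unique):
        mu = solve_mean_trajectories(model, b, time_grid)
        kk = np.exp(b)
        vals_u[r] = [flux(mu[ti], kk, float(t)) for ti, t in enumerate(time_grid)]
    vals = vals_u[inv]
    mean = vals.mean(axis=0)
    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    lower = np.minimum(np.percentile(vals, lo_q, axis=0), mean)
    upper = np.maximum(np.percentile(vals, hi_q, axis=0), mean)
    return FluxTrajectory(
        times=time_grid, mean=mean, lower=lower, upper=upper, name=flux_name, level=level
    )
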