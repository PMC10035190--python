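"""Priors: truncated multivariate normal on log rate constants and an
empirical-Bayes inverse-gamma shrinkage prior on per-isotopomer variances.

The shrinkage hyperparameters are moment-matched to the grid of per-cell
sample variances of the log data and then held fixed during sampling
(empirical Bayes): with grand mean ``sbar2`` and dispersion
``v = sum (s_it^2 - sbar2)^2 / (nT - 1)``,

    alpha* = sbar2^2 / v + 2,    kappa* = sbar2 * (alpha* - 1),

so the prior mean of sigma_i^2 equals sbar2 and alpha* > 2 by construction.
The inverse gamma is parameterized with density proportional to
x^(-alpha-1) exp(-kappa/x) (shape/scale).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import linalg

from .exceptions import DataError, DegenerateDispersionError, PriorError
from .model import TimeSeriesDataset


@dataclass
class BetaPrior:
    """Truncated multivariate normal prior on beta (log rate constants).

    ``xi`` is the prior mean, ``Lambda`` the covariance, and ``zeta_l`` /
    ``zeta_u`` elementwise truncation bounds encoding biologically plausible
    ranges.  The normalizing constant is never needed (it cancels in every
    Metropolis ratio) and is omitted from :func:`log_prior_beta`.
    """

    xi: np.ndarray
    Lambda: np.ndarray
    zeta_l: np.ndarray
    zeta_u: np.ndarray

    def __post_init__(self) -> None:
        self.xi = np.atleast_1d(np.asarray(self.xi, dtype=float))
        d = self.xi.size
        self.Lambda = np.asarray(self.Lambda, dtype=float)
        self.zeta_l = np.broadcast_to(np.asarray(self.zeta_l, dtype=float), (d,)).copy()
        self.zeta_u = np.broadcast_to(np.asarray(self.zeta_u, dtype=float), (d,)).copy()
        if self.Lambda.shape != (d, d):
            raise PriorError(f"Lambda must be ({d}, {d})")
        if not np.allclose(self.Lambda, self.Lambda.T, atol=1e-10):
            raise PriorError("Lambda must be symmetric")
        try:
            self._chol = linalg.cho_factor(self.Lambda, lower=True)
        except linalg.LinAlgError as e:
            raise PriorError(f"Lambda is not positive definite: {e}") from e
        if np.any(self.zeta_l >= self.zeta_u):
            raise PriorError("zeta_l must be elementwise below zeta_u")
        if np.any(self.xi <= self.zeta_l) or np.any(self.xi >= self.zeta_u):
            raise PriorError("prior mean xi must lie strictly inside (zeta_l, zeta_u)")

    @property
    def d(self) -> int:
        return self.xi.size

    def in_box(self, beta: np.ndarray) -> bool:
        return bool(np.all(beta >= self.zeta_l) and np.all(beta <= self.zeta_u))

    def quad_form(self, beta: np.ndarray) -> float:
        """(beta - xi)' Lambda^{-1} (beta - xi)."""
        r = np.asarray(beta, dtype=float) - self.xi
        return float(r @ linalg.cho_solve(self._chol, r))

    def marginal(self, indices: np.ndarray) -> "BetaPrior":
        """MVN marginal prior over a subset of parameters (box restricted)."""
        idx = np.asarray(indices, dtype=int)
        return BetaPrior(
            xi=self.xi[idx],
            Lambda=self.Lambda[np.ix_(idx, idx)],
            zeta_l=self.zeta_l[idx],
            zeta_u=self.zeta_u[idx],
        )

    @classmethod
    def from_ranges(
        cls,
        parameter_names: list[str],
        ranges: Mapping[str, Mapping[str, float]],
    ) -> "BetaPrior":
        """Build a diagonal prior from per-parameter range specifications.

        Each entry gives ``lower`` and ``upper`` (required) and optionally
        ``mean`` (default midpoint) and ``sd`` (default (upper-lower)/4, the
        conventional range-to-sd rule).
        """
        xi, sd, lo, up = [], [], [], []
        for p in parameter_names:
            try:
                spec = ranges[p]
            except KeyError:
                raise PriorError(f"no prior range given for parameter {p!r}") from None
            l, u = float(spec["lower"]), float(spec["upper"])
            xi.append(float(spec.get("mean", 0.5 * (l + u))))
            sd.append(float(spec.get("sd", (u - l) / 4.0)))
            lo.append(l)
            up.append(u)
        return cls(
            xi=np.array(xi),
            Lambda=np.diag(np.square(sd)),
            zeta_l=np.array(lo),
            zeta_u=np.array(up),
        )


@dataclass(frozen=True)
class ShrinkageHyperparams:
    """Inverse-gamma hyperparameters shared by all sigma_i^2."""

    alpha_star: float
    kappa_star: float

    def __post_init__(self) -> None:
        if not self.alpha_star > 2:
            raise PriorError("alpha_star must exceed 2")
        if not self.kappa_star > 0:
            raise PriorError("kappa_star must be positive")

    @property
    def prior_mean(self) -> float:
        return self.kappa_star / (self.alpha_star - 1.0)


def shrinkage_from_variances(sample_variances: np.ndarray) -> ShrinkageHyperparams:
    """Moment-match inverse-gamma hyperparameters to a grid of sample variances."""
    s2 = np.asarray(sample_variances, dtype=float).ravel()
    if s2.size < 2:
        raise DataError("need at least two sample variances")
    if np.any(s2 < 0) or not np.all(np.isfinite(s2)):
        raise DataError("sample variances must be finite and nonnegative")
    sbar = float(s2.mean())
    disp = float(np.sum((s2 - sbar) ** 2) / (s2.size - 1))
    if disp == 0.0:
        raise DegenerateDispersionError(
            "all sample variances identical; shrinkage hyperparameters undefined"
        )
    alpha = sbar * sbar / disp + 2.0
    kappa = sbar * (alpha - 1.0)
    return ShrinkageHyperparams(alpha_star=alpha, kappa_star=kappa)


def estimate_shrinkage_hyperparams(data: TimeSeriesDataset) -> ShrinkageHyperparams:
    """Empirical-Bayes hyperparameters from the per-cell variances of log y.

    Computes s_it^2 (variance over the m replicates of log y for isotopomer i
    at time t) and moment-matches the common inverse-gamma prior to the
    resulting nT-cell grid.
    """
    if data.m < 2:
        raise DataError("variance estimation needs m >= 2 replicates")
    s2 = data.log_abundances.var(axis=1, ddof=1)  # (T, n)
    return shrinkage_from_variances(s2)


def log_prior_beta(beta: np.ndarray, prior: BetaPrior) -> float:
    """Truncated-MVN log-density kernel: -1/2 quadratic form inside the box, -inf outside."""
    beta = np.asarray(beta, dtype=float)
    if beta.shape != (prior.d,):
        raise PriorError(f"beta has shape {beta.shape}, expected ({prior.d},)")
    if not prior.in_box(beta):
        return -np.inf
    return -0.5 * prior.quad_form(beta)


def log_prior_sigma2(sigma2: np.ndarray, hyper: ShrinkageHyperparams) -> float:
    """Sum of inverse-gamma log-density kernels over isotopomer variances."""
    sigma2 = np.asarray(sigma2, dtype=float)
    if np.any(sigma2 <= 0):
        return -np.inf
    return float(
        np.sum((-hyper.alpha_star - 1.0) * np.log(sigma2) - hyper.kappa_star / sigma2)
    )


def sigma2_conditional_params(
    residual_ss: float, hyper: ShrinkageHyperparams, m: int, T: int
) -> tuple[float, float]:
    """(shape, scale) of the conjugate conditional posterior of sigma_i^2."""
    if residual_ss < 0:
        raise DataError("residual sum of squares must be nonnegative")
    return hyper.alpha_star + m * T / 2.0, hyper.kappa_star + residual_ss / 2.0


def sample_sigma2_conditional(
    residual_ss: float,
    hyper: ShrinkageHyperparams,
    m: int,
    T: int,
    rng: np.random.Generator,
) -> float:
    """One conjugate draw of sigma_i^2 ~ InvGamma(alpha* + mT/2, kappa* + ss/2)."""
    shape, scale = sigma2_conditional_params(residual_ss, hyper, m, T)
    return float(scale / rng.gamma(shape))
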