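"""Posterior summarization: highest-density intervals, credible values, and
Geweke convergence diagnostics.

The credible value is a Bayesian analogue of a two-sided p-value:
p = 1 - max{alpha : null value not in HDI_alpha}.  A value below 0.05 is
treated as statistically significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

from .exceptions import DegenerateChainError, InsufficientSamplesError

if TYPE_CHECKING:  # pragma: no cover
    from .sampler import PosteriorChain

SIGNIFICANCE_LEVEL = 0.05
_BISECT_TOL = 1e-4


@dataclass(frozen=True)
class HDInterval:
    """Shortest interval containing a fraction ``level`` of the draws."""

    lower: float
    upper: float
    level: float

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass
class FluxTrajectory:
    """Pointwise posterior mean flux with central credible bounds."""

    times: np.ndarray
    mean: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    name: str
    level: float = 0.95


def _hdi_sorted(xs: np.ndarray, level: float) -> tuple[float, float]:
    """Shortest window holding ceil(level * L) consecutive sorted draws."""
    L = xs.size
    w = min(L, max(1, math.ceil(level * L)))
    if w == L:
        return float(xs[0]), float(xs[-1])
    widths = xs[w - 1 :] - xs[: L - w + 1]
    j = int(np.argmin(widths))
    return float(xs[j]), float(xs[j + w - 1])


def hdi(samples: np.ndarray, level: float = 0.95) -> HDInterval:
    """Highest-density interval under the shortest-interval convention.

    Assumes a unimodal posterior, for which the shortest contiguous window of
    sorted draws converges to the true HDI.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise InsufficientSamplesError("hdi needs at least 100 draws")
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    xs = np.sort(samples)
    lo, hi = _hdi_sorted(xs, level)
    return HDInterval(lower=lo, upper=hi, level=level)


def credible_value(samples: np.ndarray, null_value: float = 0.0) -> float:
    """1 minus the largest HDI level that excludes ``null_value``.

    Two-sided by construction: the HDI shrinks symmetrically in posterior
    density, so deviations in either direction count.  Computed by bisection
    over the level (tolerance 1e-4).
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise InsufficientSamplesError("credible_value needs at least 100 draws")
    xs = np.sort(samples)

    def excludes(level: float) -> bool:
        lo, hi = _hdi_sorted(xs, level)
        return null_value < lo or null_value > hi

    if excludes(1.0):
        return 0.0
    lo_a, hi_a = 0.0, 1.0  # invariant: excludes(lo_a) by convention, not excludes(hi_a)
    while hi_a - lo_a > _BISECT_TOL:
        mid = 0.5 * (lo_a + hi_a)
        if excludes(mid):
            lo_a = mid
        else:
            hi_a = mid
    return 1.0 - lo_a


def _spectral_variance_at_zero(x: np.ndarray) -> float:
    """Bartlett-tapered estimate of the spectral density at frequency zero."""
    n = x.size
    xc = x - x.mean()
    max_lag = min(n - 1, int(np.sqrt(n)))
    gamma0 = float(xc @ xc) / n
    s = gamma0
    for k in range(1, max_lag + 1):
        gk = float(xc[:-k] @ xc[k:]) / n
        s += 2.0 * (1.0 - k / (max_lag + 1.0)) * gk
    return max(s, gamma0 / n) if gamma0 > 0 else 0.0


def geweke_diagnostic(
    chain_column: np.ndarray, frac_first: float = 0.1, frac_last: float = 0.5
) -> float:
    """Geweke z-score comparing early vs late segment means.

    z = (mean_first - mean_last) / sqrt(S_a(0)/n_a + S_b(0)/n_b) with
    spectral-density-at-zero variance estimates; |z| < 1.96 is consistent
    with convergence.
    """
    x = np.asarray(chain_column, dtype=float).ravel()
    if x.size < 100:
        raise InsufficientSamplesError("geweke diagnostic needs a chain of length >= 100")
    if not (0 < frac_first < 1 and 0 < frac_last < 1 and frac_first + frac_last <= 1):
        raise ValueError("window fractions must be in (0,1) and sum to at most 1")
    na, nb = int(frac_first * x.size), int(frac_last * x.size)
    a, b = x[:na], x[-nb:]
    va, vb = _spectral_variance_at_zero(a), _spectral_variance_at_zero(b)
    if va <= 0 or vb <= 0:
        raise DegenerateChainError("zero-variance window; Geweke z undefined")
    return float((a.mean() - b.mean()) / np.sqrt(va / na + vb / nb))


def summarize_chain(chain: "PosteriorChain", level: float = 0.95) -> pd.DataFrame:
    """Per-parameter posterior summary: mean, sd, HDI bounds, Geweke z."""
    draws = np.asarray(chain.posterior_beta, dtype=float)
    rows = []
    for j, name in enumerate(chain.parameter_names):
        col = draws[:, j]
        interval = hdi(col, level)
        try:
            z = geweke_diagnostic(col)
        except DegenerateChainError:
            z = np.nan
        rows.append(
            {
                "parameter": name,
                "mean": float(col.mean()),
                "sd": float(col.std(ddof=1)),
                f"hdi_{level:g}_lower": interval.lower,
                f"hdi_{level:g}_upper": interval.upper,
                "geweke_z": z,
            }
        )
    return pd.DataFrame(rows)
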