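"""Exception hierarchy for kinbayes.

All package-specific errors derive from :class:`KinbayesError` so callers can
catch everything raised by the library with one clause.
"""


class KinbayesError(Exception):
    """Base class for all kinbayes errors."""


class ModelSpecError(KinbayesError):
    """Invalid kinetic model specification, or ODE states negative beyond tolerance."""


class IntegrationError(KinbayesError):
    """Numerical ODE integration failed (stiffness, blow-up, step-size collapse)."""

    def __init__(self, message: str, time: float | None = None):
        super().__init__(message)
        self.time = time


class DataError(KinbayesError):
    """Invalid observed data, or a likelihood domain violation (mu <= 0)."""


class PriorError(KinbayesError):
    """Invalid prior specification (non-SPD covariance, bad bounds, ...)."""


class DegenerateDispersionError(PriorError):
    """All sample variances identical: shrinkage hyperparameters undefined."""


class SamplerError(KinbayesError):
    """Sampler failure, e.g. a target evaluation returning NaN."""


class DegenerateChainError(KinbayesError):
    """A chain segment has zero variance; diagnostic undefined."""


class InsufficientSamplesError(KinbayesError):
    """Too few posterior draws for the requested summary."""
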