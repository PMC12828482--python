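"""Exception types shared across the package."""


class CongenialMIError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(CongenialMIError, ValueError):
    """A caller supplied an unknown label or out-of-range argument."""


class DegenerateBasisError(CongenialMIError):
    """Too few distinct values to place the requested spline knots."""


class DegenerateFitError(CongenialMIError):
    """Design matrix singular beyond ridge tolerance."""


class SmallStratumError(CongenialMIError):
    """An exposure stratum has too few observed rows to fit the imputation model."""


class SeparationError(CongenialMIError):
    """Logistic outcome contains a single class."""


class EstimationError(CongenialMIError):
    """Estimator preconditions violated (e.g. an empty exposure arm)."""


class EmptySummaryError(CongenialMIError):
    """Every replication of a scenario failed; no summary can be formed."""
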