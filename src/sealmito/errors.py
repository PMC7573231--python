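"""Exception and warning hierarchy shared across the package."""


class SealMitoError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SealMitoError, ValueError):
    """Input data violates a structural invariant."""


class ConfigError(SealMitoError, ValueError):
    """Configuration values are inconsistent or out of range."""


class InsufficientDataError(SealMitoError):
    """Too few samples to perform the requested computation."""


class MissingBaselineError(SealMitoError):
    """A run lacks the baseline steady state needed for correction."""


class NoVarianceError(SealMitoError):
    """Paired differences have zero variance; t statistic undefined."""


class UndefinedRatioError(SealMitoError, ZeroDivisionError):
    """A ratio denominator is zero or non-positive."""


class QCWarning(UserWarning):
    """Quality-control observation that does not invalidate a run."""


class ClippingWarning(QCWarning):
    """A physically impossible negative flux was clipped to zero."""
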