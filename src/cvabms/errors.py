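"""Exception hierarchy for the cvabms pipeline.

All package-specific failures derive from :class:`CvabmsError` so callers
(and the CLI) can distinguish validation problems from genuine bugs.
"""


class CvabmsError(Exception):
    """Base class for all cvabms errors."""


class ValidationError(CvabmsError, ValueError):
    """Input violates a documented precondition."""


class ShapeError(ValidationError):
    """Array dimensions are inconsistent."""


class SingularCovarianceError(CvabmsError):
    """Sensor covariance is singular (or too ill-conditioned) to invert."""


class InvalidLeadFieldError(CvabmsError):
    """Lead field is degenerate: source orientation cannot be identified."""


class UnknownModelError(ValidationError):
    """Requested feature-set dimension has no built-in band table."""


class EmptyBandError(ValidationError):
    """A frequency band contains no bins of the supplied grid."""


class DegenerateFeatureError(ValidationError):
    """A feature column has zero variance and cannot be normalized."""


class InsufficientDataError(ValidationError):
    """Too few trials to fit the requested multivariate model."""


class InconsistentDataError(ValidationError):
    """Model evidences being compared were not computed on identical data."""
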