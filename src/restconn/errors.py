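"""Exception hierarchy shared across the package.

All input-contract violations raise :class:`ValidationError` (or a more
specific subclass) so callers and the CLI can map them to a common exit code.
"""


class RestconnError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RestconnError, ValueError):
    """An input violates a documented precondition."""


class DomainError(ValidationError):
    """A value lies outside its geometric or physical domain."""


class StabilityError(ValidationError):
    """A vector-autoregressive specification is non-stationary."""


class DegenerateInputError(ValidationError):
    """An input is degenerate (constant series, zero variance, ...)."""


class BoundaryError(ValidationError):
    """A region of interest would extend past the volume boundary."""


class RankError(ValidationError):
    """A design or covariance matrix is rank deficient."""
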