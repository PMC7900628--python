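"""Exception hierarchy for contourpass.

All errors derive from :class:`ContourPassError` so callers can catch the
package's failures with a single except clause; most also derive from the
closest builtin (ValueError / RuntimeError) so generic handling keeps working.
"""


class ContourPassError(Exception):
    """Base class for all contourpass errors."""


class InvalidArgumentError(ContourPassError, ValueError):
    """An argument violates a documented precondition."""


class UnsupportedDirectionError(InvalidArgumentError):
    """Contour path angle is not a lattice direction of the hexagonal grid."""


class GeometryError(ContourPassError, ValueError):
    """A geometric construction does not fit inside the grid."""


class BalancedAssignmentError(InvalidArgumentError):
    """Balanced +/- jitter requires an even number of contour elements."""


class ConfigurationError(ContourPassError, ValueError):
    """An experiment configuration is inconsistent."""


class AlignmentError(ContourPassError, ValueError):
    """Two trial sets that must match trial-by-trial do not."""


class DegenerateFitError(ContourPassError, ValueError):
    """A regression or comparison has no information to estimate from."""


class FeasibilityError(ContourPassError, ValueError):
    """An (accuracy, agreement) pair lies outside the observer model's range."""


class InsufficientDataError(ContourPassError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedCorrelationError(ContourPassError, ValueError):
    """Correlation requested on a zero-variance variable."""


class FitError(ContourPassError, RuntimeError):
    """An iterative fit failed to converge."""


class NestingError(ContourPassError, ValueError):
    """Likelihood-ratio test requested for non-nested models."""


class SchemaError(ContourPassError, ValueError):
    """A data table does not match the expected schema."""
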