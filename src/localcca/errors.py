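"""Exception hierarchy for localcca.

All errors derive from :class:`LocalCCAError` so callers can catch the
package's failures with a single ``except`` clause; each also derives from
the closest builtin (``ValueError`` for bad inputs, ``ArithmeticError`` for
numerical breakdown) so generic handling keeps working.
"""


class LocalCCAError(Exception):
    """Base class for all localcca exceptions."""


class InvalidInputError(LocalCCAError, ValueError):
    """An argument violates a documented precondition (shape, range, order)."""


class InvalidDesignError(InvalidInputError):
    """A design matrix cannot be built (constant regressor, overlapping blocks)."""


class SingularDesignError(LocalCCAError, ValueError):
    """The design matrix is rank deficient; the message names the offending columns."""


class DegenerateNeighborhoodError(LocalCCAError, ArithmeticError):
    """A neighborhood covariance matrix is singular beyond the ridge repair."""


class NumericalFailureError(LocalCCAError, ArithmeticError):
    """An eigen/SVD solution violates its theoretical bounds beyond tolerance."""


class PerfectFitError(LocalCCAError, ArithmeticError):
    """Residual sum of squares is zero: the test statistic is unbounded."""


class InvalidParameterError(LocalCCAError, ValueError):
    """A scalar parameter (noise fraction, FWE level, ...) is out of range."""


class UndefinedRateError(LocalCCAError, ValueError):
    """ROC rates are undefined (truth all positive or all negative)."""


class UndefinedRatioError(LocalCCAError, ValueError):
    """The gray-matter confinement ratio is undefined (no detected voxels)."""
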