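"""Package-specific error types.

All inherit from :class:`ValueError` so callers that only care about
"bad input" can catch one base class.
"""


class LaterkitError(ValueError):
    """Base class for all laterkit errors."""


class InsufficientDataError(LaterkitError):
    """Too few observations to perform the requested operation."""


class DegenerateDataError(LaterkitError):
    """Data with zero variance (or otherwise degenerate) where spread is required."""


class ConvergenceError(LaterkitError):
    """An iterative fit failed to converge; carries the best iterate found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best
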