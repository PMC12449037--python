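"""Exception hierarchy shared across the package."""


class KounisPVError(Exception):
    """Base class for all package-specific errors."""


class UnknownSMQError(KounisPVError, KeyError):
    """An SMQ code was requested that the dictionary does not define."""


class FormatError(KounisPVError, ValueError):
    """Malformed input: bad ATC code, band label, or table file layout."""


class DuplicateCaseError(KounisPVError, ValueError):
    """A case identifier occurred more than once in the demographics table."""


class InfeasibleConfigError(KounisPVError, ValueError):
    """A generator configuration requests an unattainable joint distribution."""


class DegenerateTableError(KounisPVError, ValueError):
    """A 2x2 table has a zero margin, so the requested test is undefined."""


class InconsistentTableError(KounisPVError, ValueError):
    """Derived contingency-table cells came out negative."""


class SeparationError(KounisPVError, RuntimeError):
    """Complete or quasi-complete separation in a logistic fit.

    Carries the name of the offending column so callers can report which
    variable makes the maximum-likelihood estimate diverge.
    """

    def __init__(self, column: str, message: str | None = None):
        self.column = column
        super().__init__(message or f"separation detected for column {column!r}")


class ConvergenceError(KounisPVError, RuntimeError):
    """A likelihood maximisation failed to reach the gradient tolerance."""
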