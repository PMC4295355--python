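"""Exception hierarchy for tissuediff.

All exceptions derive from :class:`TissueDiffError` so callers can catch the
package's failures with a single handler; most also derive from ``ValueError``
to stay friendly to generic validation code.
"""


class TissueDiffError(Exception):
    """Base class for all tissuediff errors."""


class InvalidInputError(TissueDiffError, ValueError):
    """An argument violates a documented precondition."""


class InsufficientDataError(TissueDiffError, ValueError):
    """Too few usable data points for the requested fit."""


class DegenerateFitError(TissueDiffError, ValueError):
    """The fit converged to a physically meaningless solution (e.g. D <= 0)."""


class StrippingFailureError(TissueDiffError, ValueError):
    """Peel-off stripping left too few residual points for the fast phase."""


class OrderViolationError(TissueDiffError, ValueError):
    """Fitted fast diffusivity does not exceed the slow one."""


class UnderdeterminedDesignError(TissueDiffError, ValueError):
    """Fewer observations than regression design columns."""


class CollinearityError(TissueDiffError, ValueError):
    """Rank-deficient regression design.

    ``columns`` names the offending design columns.
    """

    def __init__(self, message: str, columns: list[str] | None = None):
        super().__init__(message)
        self.columns = columns or []


class DegenerateLabelsError(TissueDiffError, ValueError):
    """Classifier training labels contain a single class."""


class ConfigError(TissueDiffError, ValueError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(TissueDiffError, ValueError):
    """A delimited input file does not match the expected schema.

    ``missing`` lists absent required columns when applicable.
    """

    def __init__(self, message: str, missing: list[str] | None = None):
        super().__init__(message)
        self.missing = missing or []


class UndefinedStatisticError(TissueDiffError, ValueError):
    """A statistic is undefined for the given input (e.g. zero rank variance)."""
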