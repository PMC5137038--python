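"""Exception hierarchy.

All package errors derive from :class:`NiptBayesError` so callers can catch
one type at an API boundary; the subclasses distinguish user-input problems
from contract violations.
"""


class NiptBayesError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(NiptBayesError, ValueError):
    """A numeric parameter is outside its valid domain (e.g. CV <= 0)."""


class UnitsError(InvalidParameterError):
    """A value looks like a fraction/percent mix-up (e.g. CV >= 5 percent)."""


class DegeneratePriorError(InvalidParameterError):
    """Prior probability of exactly 0 or 1 leaves nothing to update."""


class PriorParseError(NiptBayesError, ValueError):
    """An odds/probability string could not be parsed."""


class TableRangeError(NiptBayesError, ValueError):
    """A risk-table query lies outside the table hull (no extrapolation)."""


class SchemaError(NiptBayesError, ValueError):
    """A batch input table is missing required columns."""


class ContractError(NiptBayesError, ValueError):
    """Caller violated an API contract (e.g. mismatched calibration setup)."""
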