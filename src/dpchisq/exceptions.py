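"""Exception hierarchy.

Errors are split into three families so callers (and the CLI exit codes) can
distinguish bad input data, bad configuration, and numerical failures.
"""


class DpChisqError(Exception):
    """Base class for all package errors."""


class TableError(DpChisqError, ValueError):
    """Invalid contingency-table input."""


class DimensionError(TableError):
    """Table smaller than 2x2."""


class InvalidCountError(TableError):
    """Negative, non-integer, or all-zero counts."""


class ZeroMarginError(TableError):
    """A row or column margin is zero, so expected counts are undefined."""


class TableFormatError(TableError):
    """Malformed CSV input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class SensitivityError(DpChisqError, ValueError):
    """Invalid arguments to a sensitivity formula."""


class EnumerationBudgetError(SensitivityError):
    """Brute-force enumeration would exceed the table budget."""


class NumericalError(DpChisqError, RuntimeError):
    """Base class for quadrature / root-finding failures."""


class QuadratureError(NumericalError):
    """Adaptive quadrature did not reach the requested tolerance."""

    def __init__(self, message: str, achieved: float | None = None):
        self.achieved = achieved
        super().__init__(message)


class BracketError(NumericalError):
    """Root bracketing failed; indicates a quadrature fault upstream."""


class ConfigError(DpChisqError, ValueError):
    """Invalid simulation / CLI configuration."""
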