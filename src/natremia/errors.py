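"""Exception hierarchy shared across the package."""


class NatremiaError(Exception):
    """Base class for all package errors."""


class InvalidInputError(NatremiaError, ValueError):
    """A physiological or infusate parameter is out of its valid domain."""


class CohortParseError(NatremiaError, ValueError):
    """A cohort file could not be parsed; carries row/column context."""

    def __init__(self, message: str, row: int | None = None, column: str | None = None):
        self.row = row
        self.column = column
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        super().__init__(f"{message}" + (f" ({', '.join(loc)})" if loc else ""))


class UndefinedStatisticError(NatremiaError, ValueError):
    """A statistic is undefined for the given inputs (e.g. constant vector)."""
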