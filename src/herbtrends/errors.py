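"""Exception hierarchy shared across the pipeline."""

from __future__ import annotations


class HerbTrendsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HerbTrendsError):
    """A run configuration, column map, or unit declaration is invalid."""


class TableFormatError(HerbTrendsError):
    """An input table violates its format contract.

    ``rows`` carries 1-based line numbers of the offending rows (the
    header is line 1) so the message can point at the exact cells.
    """

    def __init__(self, message: str, rows: list[int] | None = None):
        self.rows = rows or []
        if self.rows:
            message = f"{message} (lines: {', '.join(map(str, self.rows))})"
        super().__init__(message)


class ValidationError(HerbTrendsError):
    """A record violates a domain invariant."""


class MissingDataError(HerbTrendsError):
    """A required record (e.g. a planted-area entry) is absent."""
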