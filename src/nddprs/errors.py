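"""Exception hierarchy.

Validation-type errors (bad config, malformed input, failed joins) are kept
distinct from runtime errors so the command-line layer can map them to
different exit codes (2 vs 3).
"""


class NddprsError(Exception):
    """Base class for all package errors."""


class ConfigError(NddprsError, ValueError):
    """Invalid configuration value (non-positive count, correlation out of range, ...)."""


class ValidationError(NddprsError, ValueError):
    """Input table fails a contract: missing column, mismatched keys, p outside [0,1]."""


class ParseError(NddprsError):
    """A file does not parse under its declared format."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class EmptyPanelError(NddprsError):
    """Every variant (or gene) was removed by filtering."""


class InsufficientCohortError(NddprsError):
    """Fewer samples remain than an analysis requires."""


class EnumerationCapError(NddprsError):
    """Exact enumeration would exceed the configured table cap; use Monte-Carlo mode."""
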