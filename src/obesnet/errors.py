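"""Package exception types."""


class ObesnetError(Exception):
    """Base class for package errors."""


class ConfigurationError(ObesnetError):
    """Invalid configuration: bad distribution parameters, missing tables,
    probabilities that do not sum to one, unknown labels, ..."""


class ParseError(ObesnetError):
    """Malformed input file.  Carries the offending row where known."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"{message} (row {row})"
        super().__init__(message)


class ExtinctionError(ObesnetError):
    """Raised when the simulated population dies out entirely."""
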