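"""Exception hierarchy shared across the package."""


class AssocnetError(Exception):
    """Base class for all package errors."""


class ParseError(AssocnetError):
    """Malformed input in any of the supported text formats.

    ``line`` is 1-based when the format is line-oriented and the offending
    line is known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ValidationError(AssocnetError):
    """A domain object violates one of its invariants."""


class SaturationError(AssocnetError):
    """A distance correction is undefined for the observed divergence."""
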