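"""Exception types shared across the package."""


class IntergenicError(Exception):
    """Base class for all package errors."""


class AnnotationParseError(IntergenicError):
    """A gene-annotation source could not be parsed.

    Carries the 1-based line number of the offending record when known.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class OrderingError(IntergenicError):
    """An operation that requires a sorted universe received an unsorted one."""


class ValidationError(IntergenicError):
    """An input value violates a documented precondition."""


class NormalizationError(IntergenicError):
    """Expression normalization failed (e.g. a sample with zero median)."""
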