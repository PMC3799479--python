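"""Exception hierarchy.

``ParseError`` and ``ValidationError`` signal bad input data (CLI exit 2);
``ContractViolation`` signals an internal precondition breach (CLI exit 1).
"""


class PiswapError(Exception):
    """Base class for all piswap errors."""


class ParseError(PiswapError):
    """A file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += str(path)
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ValidationError(PiswapError):
    """Input data violates a domain invariant (e.g. negative score)."""


class InjectivityError(ValidationError):
    """A mapping repeats an endpoint on either side."""


class ContractViolation(PiswapError):
    """An operation was called outside its precondition."""
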