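"""Typed exceptions shared across the package."""


class MagfuncError(Exception):
    """Base class for all package errors."""


class DefinitionParseError(MagfuncError):
    """A module definition string could not be parsed.

    Parameters
    ----------
    message : str
        Human-readable description of the problem.
    offset : int
        Character offset into the definition string where the problem was
        detected.
    """

    def __init__(self, message: str, offset: int):
        super().__init__(f"{message} (offset {offset})")
        self.offset = offset


class FormatError(MagfuncError):
    """An input file violates its expected tabular/record format."""

    def __init__(self, message: str, path=None, line=None):
        loc = ""
        if path is not None:
            loc += f" [{path}"
            loc += f":{line}]" if line is not None else "]"
        super().__init__(message + loc)
        self.path = path
        self.line = line


class DegenerateDenominatorError(MagfuncError):
    """A normalization denominator (SCG mean or library size) is zero."""


class ValidationError(MagfuncError):
    """Inputs are structurally valid but semantically inconsistent."""
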