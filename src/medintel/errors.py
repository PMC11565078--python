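"""Exception hierarchy.

Every error the toolkit raises deliberately derives from :class:`MedIntelError`,
so callers (and the CLI) can distinguish "bad input" from a genuine bug.
"""

from __future__ import annotations


class MedIntelError(Exception):
    """Base class for all errors raised by this package."""


class StructuralError(MedIntelError):
    """A JSON tree is not a FHIR resource at all (e.g. no ``resourceType``)."""


class FieldValidationError(MedIntelError):
    """A resource field failed validation.

    Parameters
    ----------
    path:
        Dotted JSON path of the offending member, e.g.
        ``"valueQuantity.value"``.
    message:
        Human-readable description of what was wrong.
    """

    def __init__(self, path: str, message: str):
        self.path = path
        self.message = message
        super().__init__(f"{path}: {message}")


class NdjsonLineError(MedIntelError):
    """A line of an NDJSON file could not be parsed.

    Carries the 1-based line number and the underlying cause.
    """

    def __init__(self, line_no: int, cause: Exception):
        self.line_no = line_no
        self.cause = cause
        super().__init__(f"line {line_no}: {cause}")


class PathSyntaxError(MedIntelError):
    """A flattening path expression failed to compile.

    ``position`` is the 0-based character offset of the error; the string
    form renders a caret under the offending character.
    """

    def __init__(self, expr: str, position: int, message: str):
        self.expr = expr
        self.position = position
        self.message = message
        caret = " " * position + "^"
        super().__init__(f"{message} at position {position}\n  {expr}\n  {caret}")


class QueryError(MedIntelError):
    """A search query used an unsupported parameter or malformed filter."""


class ConfigError(MedIntelError):
    """A configuration file or block is invalid or missing."""


class ContractError(MedIntelError):
    """An operation was called in a way its contract forbids."""
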