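"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`IfacemutError`,
so callers (and the CLI) can distinguish bad input from genuine bugs.
"""


class IfacemutError(Exception):
    """Base class for all package errors."""


class FormatError(IfacemutError):
    """A file could not be parsed in the declared format."""


class EmptyStructureError(IfacemutError):
    """A structure file contained no protein atoms."""


class RadiiError(IfacemutError):
    """An element has no van der Waals radius and the fallback is disabled."""


class ConsistencyError(IfacemutError):
    """A profile or table does not match the structure it is used with."""


class GeometryError(IfacemutError):
    """A geometric query could not be answered (e.g. no qualifying atoms)."""


class ParseError(FormatError):
    """A tabular file had a malformed row; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class MissingDataError(IfacemutError):
    """A candidate substitution has no stability record."""


class NormalizationError(IfacemutError):
    """Expression counts could not be normalized (e.g. zero reference count)."""


class InsufficientControlsError(IfacemutError):
    """Fewer than two control samples were supplied for threshold estimation."""


class RecipeError(IfacemutError):
    """A synthetic-data recipe is internally inconsistent or infeasible."""


class ConfigError(IfacemutError):
    """A run configuration document is invalid."""
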