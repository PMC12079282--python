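"""Exception hierarchy shared across the package."""


class CatqsprError(Exception):
    """Base class for all package errors."""


class StructureParseError(CatqsprError):
    """Malformed XYZ / MOL V2000 input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


class PropertyLookupError(CatqsprError, KeyError):
    """Unknown (element, property) pair in the atomic property tables."""


class ParameterizationError(CatqsprError):
    """An element lacks required parameters (PEOE, covalent radius, ...)."""


class ConfigurationError(CatqsprError):
    """Unknown registry token, malformed descriptor name or cutoff window."""


class DomainError(CatqsprError, ValueError):
    """Input outside the mathematical domain of an operation."""


class SingularityError(CatqsprError):
    """Rank-deficient design matrix or degenerate leverage."""
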