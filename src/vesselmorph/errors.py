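"""Exception types shared across the package."""


class VesselmorphError(Exception):
    """Base class for all package-specific errors."""


class SkeletonFormatError(VesselmorphError, ValueError):
    """A skeleton file violates its format contract.

    Carries the offending line number when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnsupportedStructureError(VesselmorphError, ValueError):
    """The graph topology cannot be represented in the requested format."""


class DegenerateGeometryError(VesselmorphError, ValueError):
    """Input geometry is degenerate (e.g. coincident consecutive points)."""


class ParameterError(VesselmorphError, ValueError):
    """A parameter is outside its valid range."""


class InsufficientDataError(VesselmorphError, ValueError):
    """Too few observations for the requested statistic."""
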