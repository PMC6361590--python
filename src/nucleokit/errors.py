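"""Exception types shared across the package."""


class NucleokitError(Exception):
    """Base class for package-specific failures."""


class ParameterError(NucleokitError, ValueError):
    """An input parameter is outside its valid domain."""


class InvalidRangeError(NucleokitError, ValueError):
    """A requested sampling or fitting range is empty or inverted."""


class GeometryError(NucleokitError, ValueError):
    """A geometric constraint is violated (e.g. cluster does not fit in field)."""


class FitError(NucleokitError, RuntimeError):
    """A regression could not be performed (too few bins, rank deficiency)."""


class ConvergenceError(NucleokitError, RuntimeError):
    """An iterative procedure failed to converge; carries the iteration history."""

    def __init__(self, message, history=None):
        super().__init__(message)
        self.history = history or []


class RangeCollapseError(NucleokitError, RuntimeError):
    """The self-consistent fitting window shrank below the lower cutoff."""


class SchemaError(NucleokitError, ValueError):
    """A table is missing required columns."""


class RowError(NucleokitError, ValueError):
    """One or more rows of a table are malformed; carries the line numbers."""

    def __init__(self, message, lines=None):
        super().__init__(message)
        self.lines = lines or []


class RateModelError(NucleokitError, ValueError):
    """Kinetic rates overflow or are otherwise unusable."""
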