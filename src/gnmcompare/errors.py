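"""Exception hierarchy for gnmcompare."""


class GnmCompareError(Exception):
    """Base class for all package-specific errors."""


class InputError(GnmCompareError):
    """A source file is missing or unreadable."""


class ParseError(GnmCompareError):
    """A structure file could not be parsed; message carries record context."""


class EmptyStructureError(GnmCompareError):
    """A parsed file contained no ATOM/HETATM records."""


class EmptySelectionError(GnmCompareError):
    """An atom selection matched nothing where at least one atom is required."""


class SelectionError(GnmCompareError):
    """A selection referenced a chain or residue that does not exist."""


class InvariantError(GnmCompareError):
    """A computed object violated one of its declared invariants."""


class UndefinedCorrelationError(GnmCompareError):
    """Pearson correlation requested on a zero-variance vector."""


class DegenerateSuperpositionError(GnmCompareError):
    """Superposition impossible: too few pairs or all pairs rejected."""


class GeometryError(GnmCompareError):
    """A synthetic-geometry request cannot be satisfied."""


class PlacementError(GeometryError):
    """Random placement failed after bounded retries."""


class PipelineError(GnmCompareError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
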