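"""Exception hierarchy for mdcompare.

All package-specific errors derive from :class:`MDCompareError` so callers
can catch everything with one clause while still distinguishing parse
problems from geometric or statistical ones.
"""


class MDCompareError(Exception):
    """Base class for all mdcompare errors."""


class ParseError(MDCompareError):
    """A file could not be parsed; the message names the offending line."""


class EmptyStructureError(ParseError):
    """A structure file contained no atoms."""


class SelectionSyntaxError(MDCompareError):
    """Invalid atom-selection expression.

    Carries ``position``, the 0-based character offset of the error.
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position


class TopologyMismatchError(MDCompareError):
    """Trajectory atom count does not match the topology."""


class GeometryError(MDCompareError):
    """Degenerate coordinates (e.g. coincident donor and acceptor)."""


class SuperpositionError(MDCompareError):
    """Rigid superposition is undefined (too few or collinear atoms)."""


class ConvergenceError(MDCompareError):
    """Iterative procedure failed to converge within its iteration cap."""


class ComparabilityError(MDCompareError):
    """Two results were computed under incompatible settings."""


class DataError(MDCompareError):
    """Input data violate a precondition (e.g. non-positive intensity)."""


class GeneratorSpecError(MDCompareError):
    """Synthetic-data generator specification is invalid."""
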