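"""Exception hierarchy."""


class PipgateError(Exception):
    """Base class for all package errors."""


class StructureParseError(PipgateError):
    """A structure or trajectory file could not be parsed."""


class TrajectoryError(PipgateError):
    """Trajectory contents violate a precondition (atom counts, frames)."""


class SelectionQueryError(PipgateError):
    """An atom-selection expression is syntactically invalid."""


class PocketAssignmentError(PipgateError):
    """Lipid-to-pocket assignment failed (wrong lipid count, ambiguity)."""


class GeometryError(PipgateError):
    """Degenerate geometry (too few points, collinear sets, zero axis)."""


class MissingResidueError(PipgateError):
    """Required residues or atoms are absent from a structure."""


class TraceError(PipgateError):
    """A recording trace violates a precondition (epochs, events, length)."""


class FitError(PipgateError):
    """A model fit failed to converge."""


class ConfigError(PipgateError):
    """Run configuration invalid; carries the accumulated error list."""

    def __init__(self, errors):
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))
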