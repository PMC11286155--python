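"""Exception types shared across the package."""


class DomainError(ValueError):
    """A parameter or argument is outside its physical/valid domain."""


class ResolutionError(ValueError):
    """Voxel pitch too coarse to resolve a geometric feature."""


class EmptySectionError(ValueError):
    """A sectioning plane does not intersect the muscle mask."""


class FitError(ValueError):
    """Regression cannot be performed on the given data."""


class DegenerateDirectionError(ValueError):
    """A muscle vector has coincident origin and insertion."""


class MeshQualityError(ValueError):
    """An element is inverted or otherwise unusable for assembly."""


class NodeSetLookupError(KeyError):
    """A required named node set or probe is missing from the mesh."""


class SingularSystemError(RuntimeError):
    """The constrained stiffness system is singular (rigid modes remain)."""


class SolverError(RuntimeError):
    """The linear solve failed to meet its residual bound."""


class DegeneracyError(RuntimeError):
    """A sensitivity solve is degenerate (zero influence at the control node)."""
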