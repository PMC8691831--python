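"""Exception hierarchy shared across the package."""


class CleaveKitError(Exception):
    """Base class for all package-specific errors."""


class GeometryError(CleaveKitError, ValueError):
    """A geometric precondition failed (line misses contour, etc.)."""


class InvalidContourError(GeometryError):
    """Polygon is degenerate, self-intersecting, or has too few vertices."""


class InvalidPoseError(GeometryError):
    """Spindle pose violates its invariants (coincident poles, plate off-axis)."""


class NoSplitError(GeometryError):
    """A cut line/plane does not pass through the shape interior."""


class AmbiguousSideError(GeometryError):
    """A reference point lies on the cut, so sides cannot be assigned."""


class ConvergenceError(CleaveKitError, RuntimeError):
    """An iterative geometric procedure failed to converge."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class MeshIntegrityError(CleaveKitError, ValueError):
    """Triangle mesh is open, inconsistently oriented, or inverted."""


class ParameterError(CleaveKitError, ValueError):
    """Invalid user-supplied parameter value."""


class DegenerateTestError(CleaveKitError, ValueError):
    """A statistical test has no effective observations."""
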