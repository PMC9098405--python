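"""Exception hierarchy for zmo."""


class ZmoError(Exception):
    """Base class for all zmo errors."""


class ValidationError(ZmoError):
    """Invalid input data (missing landmarks, non-binary mask, bad shapes)."""


class DegenerateFrameError(ZmoError):
    """Head-frame construction failed (collinear landmarks, ambiguous axes)."""


class OrientationError(ZmoError):
    """Landmark labels inconsistent with the expected anatomical orientation."""


class AlignmentError(ZmoError):
    """Rigid landmark alignment is under-determined or degenerate."""


class SliceError(ZmoError):
    """A requested cross-section does not intersect the mask."""


class RayMissError(ZmoError):
    """A construction ray failed to intersect the target contour."""

    def __init__(self, message: str, angle_deg: float | None = None):
        super().__init__(message)
        self.angle_deg = angle_deg


class DegenerateSpanError(ZmoError):
    """The angular span between the bounding landmarks is empty."""


class PhantomSizingError(ZmoError):
    """A phantom structure does not fit inside the requested grid."""

    def __init__(self, structure: str, message: str | None = None):
        super().__init__(message or f"structure {structure!r} exceeds the phantom grid")
        self.structure = structure
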