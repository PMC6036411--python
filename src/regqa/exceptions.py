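"""Exception hierarchy for registration-QA errors."""


class RegQAError(Exception):
    """Base class for all package errors."""


class InvalidShiftError(RegQAError):
    """Patient-shift specification does not cover three orthogonal axes exactly once."""


class DirectionMismatchError(RegQAError):
    """Two transforms (or a transform and a reference) disagree on mapping direction."""


class NotRigidError(RegQAError):
    """A matrix expected to be a proper rotation fails orthonormality/determinant checks."""


class ParseError(RegQAError):
    """A registration object, landmark file or mask could not be parsed."""


class AmbiguousMatrixError(ParseError):
    """Raw scan found several candidate 16-value matrix runs; the caller must select one."""

    def __init__(self, candidates):
        self.candidates = candidates
        super().__init__(
            f"found {len(candidates)} candidate 4x4 matrix runs; "
            "pass select=<index> to choose one"
        )


class GeometryError(RegQAError):
    """Grid geometries are inconsistent (mismatched dims/spacing/origin, bad metadata)."""


class OutOfGridError(RegQAError):
    """A point falls outside the voxel-centre hull of a displacement grid."""

    def __init__(self, points, message=None):
        self.points = points
        super().__init__(message or f"{len(points)} point(s) outside the DVF grid hull")


class UndefinedMetricError(RegQAError):
    """A metric is undefined for the given inputs (e.g. Dice of two empty volumes)."""
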