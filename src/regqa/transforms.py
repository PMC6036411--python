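"""Rigid-transform construction and error metrics for registration QA.

Everything here works in the DICOM patient coordinate system (LPS): a
right-handed frame with +x toward the patient's left, +y posterior and +z
superior, units of millimetres.  A rigid registration is represented by a
4x4 homogeneous matrix

    [ R  T ]
    [ 0  1 ]

whose rotation block ``R`` is a proper rotation and whose last column ``T``
is the translation in mm.  DICOM spatial registration objects store this
matrix row-major; note that it maps points of the *target* (stationary)
frame into the *moving* frame, i.e. it points opposite to the registration
direction a user selects in the software.

The QA procedure implemented here builds an independent *nominal* transform
from the known phantom shifts and rotations, inverts it into the direction
the registration object reports, and compares:

* per-axis translation errors against the half-voxel tolerance, and
* the axis of the composite rotation (the real eigenvector of ``R``)
  against the nominal axis, the angle between them quantifying overall
  rotational misalignment.

Angles cross the public interface in degrees; radians are internal only.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .exceptions import DirectionMismatchError, InvalidShiftError, NotRigidError

__all__ = [
    "Direction",
    "PatientShift",
    "RotationSpec",
    "HomogeneousTransform",
    "RotationAxis",
    "patient_shift_to_dicom",
    "expected_translation",
    "rotation_about_axis",
    "compose_rotations",
    "build_nominal_transform",
    "invert_transform",
    "translation_errors",
    "transform_point",
    "rotation_axis",
    "axis_misalignment",
    "half_voxel_check",
    "error_at_point",
]

_ORTHO_ATOL = 1e-9

#: patient-direction vocabulary -> (axis index, sign) in DICOM LPS
_DIRECTION_VOCAB = {
    "lt": (0, +1.0), "left": (0, +1.0), "l": (0, +1.0),
    "rt": (0, -1.0), "right": (0, -1.0), "r": (0, -1.0),
    "post": (1, +1.0), "posterior": (1, +1.0), "p": (1, +1.0),
    "ant": (1, -1.0), "anterior": (1, -1.0), "a": (1, -1.0),
    "sup": (2, +1.0), "superior": (2, +1.0), "s": (2, +1.0),
    "inf": (2, -1.0), "inferior": (2, -1.0), "i": (2, -1.0),
}


class Direction(enum.Enum):
    """Which way a homogeneous transform maps points."""

    TARGET_TO_MOVING = "target_to_moving"
    MOVING_TO_STATIONARY = "moving_to_stationary"
    UNSPECIFIED = "unspecified"

    def flipped(self) -> "Direction":
        if self is Direction.TARGET_TO_MOVING:
            return Direction.MOVING_TO_STATIONARY
        if self is Direction.MOVING_TO_STATIONARY:
            return Direction.TARGET_TO_MOVING
        return Direction.UNSPECIFIED


class ShiftedRole(enum.Enum):
    """Which dataset of the registration pair was physically shifted."""

    STATIONARY = "stationary_is_shifted"
    MOVING = "moving_is_shifted"


@dataclass(frozen=True)
class PatientShift:
    """A known phantom displacement expressed in patient-direction terms.

    Parameters
    ----------
    components
        Three ``(magnitude_mm, direction)`` pairs, e.g.
        ``[(10, "Lt"), (5, "Ant"), (15, "Sup")]``.  Directions use the
        clinical vocabulary Lt/Rt, Ant/Post, Sup/Inf (case-insensitive,
        full words accepted).  The three pairs must cover the three
        anatomical axes exactly once.
    shifted_role
        Whether the stationary (target) or the moving dataset is the one
        that was shifted; this fixes the sign of the expected translation.
    """

    components: tuple = ()
    shifted_role: ShiftedRole | None = None

    def __post_init__(self):
        comps = tuple((float(m), str(d)) for m, d in self.components)
        object.__setattr__(self, "components", comps)
        if len(comps) != 3:
            raise InvalidShiftError(f"need exactly 3 components, got {len(comps)}")
        axes = []
        for mag, label in comps:
            key = label.strip().lower().rstrip(".")
            if key not in _DIRECTION_VOCAB:
                raise InvalidShiftError(f"unknown patient direction {label!r}")
            if not np.isfinite(mag):
                raise InvalidShiftError(f"non-finite shift magnitude {mag!r}")
            axes.append(_DIRECTION_VOCAB[key][0])
        if sorted(axes) != [0, 1, 2]:
            raise InvalidShiftError(
                f"shift directions must cover x, y, z exactly once, got axes {axes}"
            )

    @classmethod
    def zero(cls, shifted_role: ShiftedRole | None = None) -> "PatientShift":
        return cls(((0.0, "Lt"), (0.0, "Post"), (0.0, "Sup")), shifted_role)


@dataclass(frozen=True)
class RotationSpec:
    """Known rotation angles about the DICOM x, y, z axes, in degrees."""

    angle_x: float = 0.0
    angle_y: float = 0.0
    angle_z: float = 0.0

    def __post_init__(self):
        for name in ("angle_x", "angle_y", "angle_z"):
            a = float(getattr(self, name))
            if not np.isfinite(a) or not (-180.0 < a <= 180.0):
                raise ValueError(f"{name}={a!r} must be finite and in (-180, 180]")
            object.__setattr__(self, name, a)


def _as_point(p) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if p.shape != (3,):
        raise ValueError(f"expected a 3-vector, got shape {p.shape}")
    return p


def check_rotation(r: np.ndarray, atol: float = _ORTHO_ATOL, warn_only: bool = False) -> None:
    """Verify ``r`` is a proper rotation (orthonormal, det = +1).

    Matrices read from files are rounded to a few decimals, so callers may
    downgrade the check to a warning with ``warn_only=True``.
    """
    r = np.asarray(r, dtype=float)
    dev = float(np.max(np.abs(r @ r.T - np.eye(3))))
    ddev = abs(float(np.linalg.det(r)) - 1.0)
    if dev > atol or ddev > atol:
        msg = (f"rotation block deviates from orthonormality by {dev:.2e} "
               f"(|det-1| = {ddev:.2e})")
        if warn_only:
            warnings.warn(msg, stacklevel=3)
        else:
            raise NotRigidError(msg)


@dataclass
class HomogeneousTransform:
    """A 4x4 rigid transform: rotation block plus translation column (mm)."""

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: Direction = Direction.UNSPECIFIED

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)
        if not (np.all(np.isfinite(self.rotation)) and np.all(np.isfinite(self.translation))):
            raise ValueError("transform contains non-finite values")

    # -- conversions ----------------------------------------------------
    @property
    def matrix(self) -> np.ndarray:
        """The full 4x4 matrix with exact (0,0,0,1) bottom row."""
        m = np.eye(4)
        m[:3, :3] = self.rotation
        m[:3, 3] = self.translation
        return m

    @classmethod
    def from_matrix(cls, m, direction: Direction = Direction.UNSPECIFIED,
                    rigid_atol: float | None = None) -> "HomogeneousTransform":
        m = np.asarray(m, dtype=float).reshape(4, 4)
        if not np.allclose(m[3], [0, 0, 0, 1], atol=1e-12):
            raise ValueError(f"bottom row must be (0,0,0,1), got {m[3]}")
        t = cls(m[:3, :3], m[:3, 3], direction)
        if rigid_atol is not None:
            check_rotation(t.rotation, atol=rigid_atol, warn_only=True)
        return t

    def to_flat(self) -> list[float]:
        """Row-major 16-value list, the DICOM serialization order."""
        return [float(v) for v in self.matrix.ravel()]

    @classmethod
    def from_flat(cls, values: Sequence[float],
                  direction: Direction = Direction.UNSPECIFIED) -> "HomogeneousTransform":
        vals = [float(v) for v in values]
        if len(vals) != 16:
            raise ValueError(f"need 16 values, got {len(vals)}")
        return cls.from_matrix(np.asarray(vals).reshape(4, 4), direction)

    @classmethod
    def identity(cls, direction: Direction = Direction.UNSPECIFIED) -> "HomogeneousTransform":
        return cls(np.eye(3), np.zeros(3), direction)

    # -- algebra --------------------------------------------------------
    def apply(self, p) -> np.ndarray:
        """Map a point (or an (n,3) array of points): ``R p + T``."""
        p = np.asarray(p, dtype=float)
        return p @ self.rotation.T + self.translation

    def compose(self, other: "HomogeneousTransform") -> "HomogeneousTransform":
        """``self ∘ other``: apply ``other`` first, then ``self``."""
        return HomogeneousTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
            self.direction,
        )

    def __matmul__(self, other):
        if isinstance(other, HomogeneousTransform):
            return self.compose(other)
        return NotImplemented

    def inverse(self) -> "HomogeneousTransform":
        return invert_transform(self)

    def is_close(self, other: "HomogeneousTransform", atol: float = 1e-9) -> bool:
        return bool(np.allclose(self.matrix, other.matrix, atol=atol))


def patient_shift_to_dicom(shift: PatientShift) -> np.ndarray:
    """Convert a patient-direction shift to a DICOM LPS displacement vector.

    Left maps to +x, Posterior to +y, Superior to +z; the opposite
    directions negate.  The result is the displacement of the *shifted*
    dataset, in mm, before any account of registration direction.
    """
    v = np.zeros(3)
    for mag, label in shift.components:
        axis, sign = _DIRECTION_VOCAB[label.strip().lower().rstrip(".")]
        v[axis] = sign * mag
    return v


def expected_translation(shift: PatientShift) -> np.ndarray:
    """Known translation ``T`` in the direction the DICOM object reports.

    The registration object maps target-frame points into the moving frame,
    opposite to the registration direction.  When the stationary (target)
    dataset is the one that was shifted, the reported ``T`` is the negated
    shift; when the moving dataset was shifted, signs are kept.
    """
    if shift.shifted_role is None:
        raise InvalidShiftError("shifted_role must be set to derive the expected translation")
    v = patient_shift_to_dicom(shift)
    return -v if shift.shifted_role is ShiftedRole.STATIONARY else v


def rotation_about_axis(axis: str, angle_deg: float) -> np.ndarray:
    """Single-axis rotation matrix in the element layout used by the QA worksheets.

    ``axis`` is one of ``"x" | "y" | "z"``.  Note that the y-axis matrix
    places ``-sin`` at row 1, column 3 — the transpose of the textbook
    convention.  This is deliberate: the composite built from these layouts
    is what the nominal worked example is defined by, and the whole QA
    chain (inversion, eigen-axis) is anchored to it.
    """
    a = np.deg2rad(float(angle_deg))
    c, s = np.cos(a), np.sin(a)
    axis = axis.lower()
    if axis == "x":
        return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
    if axis == "y":
        return np.array([[c, 0, -s], [0, 1, 0], [s, 0, c]])
    if axis == "z":
        return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])
    raise ValueError(f"axis must be 'x', 'y' or 'z', got {axis!r}")


def compose_rotations(spec: RotationSpec, order: str = "zyx") -> np.ndarray:
    """Compose the three single-axis rotations into one matrix.

    ``order`` names the matrix product left to right: the default
    ``"zyx"`` builds ``Rz @ Ry @ Rx``.  This product, with the element
    layouts of :func:`rotation_about_axis`, is the one that reproduces
    the nominal phantom worked example; other orders are available for
    sensitivity checks.
    """
    angles = {"x": spec.angle_x, "y": spec.angle_y, "z": spec.angle_z}
    if sorted(order.lower()) != ["x", "y", "z"]:
        raise ValueError(f"order must be a permutation of 'xyz', got {order!r}")
    r = np.eye(3)
    for ax in order.lower():
        r = r @ rotation_about_axis(ax, angles[ax])
    return r


def build_nominal_transform(spec: RotationSpec, shift: PatientShift,
                            order: str = "zyx") -> HomogeneousTransform:
    """Independent ground-truth transform from the moving to the stationary frame.

    Rotations are applied first, then the translation, so the translation
    column is exactly the patient shift in LPS mm.  Compare against a
    registration object by inverting this transform (the object reports
    the opposite, target-to-moving direction).
    """
    return HomogeneousTransform(
        compose_rotations(spec, order=order),
        patient_shift_to_dicom(shift),
        Direction.MOVING_TO_STATIONARY,
    )


def invert_transform(t: HomogeneousTransform) -> HomogeneousTransform:
    """Exact inverse; for a rigid transform this is ``(Rᵀ, -Rᵀ T)``.

    Falls back to a general 4x4 inverse for slightly non-orthonormal
    matrices read from files; a singular matrix raises.
    """
    r, tv = t.rotation, t.translation
    dev = float(np.max(np.abs(r @ r.T - np.eye(3))))
    if dev <= 1e-9:
        rinv = r.T
        tinv = -rinv @ tv
    else:
        m = np.linalg.inv(t.matrix)  # raises LinAlgError when singular
        rinv, tinv = m[:3, :3], m[:3, 3]
    return HomogeneousTransform(rinv, tinv, t.direction.flipped())


def transform_point(t: HomogeneousTransform, p) -> np.ndarray:
    """Apply ``t`` to a point: ``R p + T``."""
    return t.apply(_as_point(p))


def translation_errors(reported: HomogeneousTransform, known) -> np.ndarray:
    """Per-axis registration errors: reported translation minus known ``T``.

    Both the reported transform and the known translation must be in the
    target-to-moving direction (the one the registration object stores);
    a tagged transform in the opposite direction raises rather than
    silently producing sign-flipped errors.
    """
    if reported.direction is Direction.MOVING_TO_STATIONARY:
        raise DirectionMismatchError(
            "reported transform is tagged moving_to_stationary; invert it (or its "
            "nominal counterpart) so both are target_to_moving before differencing"
        )
    return reported.translation - _as_point(known)


def error_at_point(nominal: HomogeneousTransform, reported: HomogeneousTransform,
                   p=(0.0, 0.0, 0.0)) -> np.ndarray:
    """Registration error vector at a specific point.

    Translation errors taken from the matrix columns are exact only at the
    origin; at any other point the angular misalignment contributes.  Both
    transforms must map the same direction.
    """
    if (nominal.direction is not Direction.UNSPECIFIED
            and reported.direction is not Direction.UNSPECIFIED
            and nominal.direction is not reported.direction):
        raise DirectionMismatchError(
            f"nominal is {nominal.direction.value}, reported is {reported.direction.value}"
        )
    p = _as_point(p)
    return nominal.apply(p) - reported.apply(p)


@dataclass(frozen=True)
class RotationAxis:
    """Unit axis of a composite rotation, with a flag for the degenerate case.

    For the identity (rotation angle ~ 0) the axis is undefined;
    ``degenerate`` is then True and ``vector`` is a placeholder +z so that
    downstream misalignment reporting can proceed with an explicit warning
    instead of failing the whole QA run.
    """

    vector: np.ndarray
    angle_deg: float
    degenerate: bool = False


def rotation_axis(r: np.ndarray, degenerate_angle_deg: float = 1e-7) -> RotationAxis:
    """Axis of rotation of ``r``: the real unit eigenvector with eigenvalue +1.

    A 3x3 proper rotation has exactly one real eigenvector (up to sign);
    it spans the line left unchanged by the rotation.  The sign is
    canonicalized so the component of largest magnitude is positive —
    numerical eigensolvers return an arbitrary sign, so comparisons
    between axes must anyway be sign-blind (see :func:`axis_misalignment`).

    The rotation angle is recovered from the trace,
    ``cos(theta) = (tr(R) - 1)/2``; below ``degenerate_angle_deg`` the axis
    is flagged undefined.
    """
    r = np.asarray(r, dtype=float).reshape(3, 3)
    check_rotation(r, atol=1e-3, warn_only=True)
    cos_th = np.clip((np.trace(r) - 1.0) / 2.0, -1.0, 1.0)
    angle = float(np.degrees(np.arccos(cos_th)))
    if angle < degenerate_angle_deg:
        return RotationAxis(np.array([0.0, 0.0, 1.0]), angle, degenerate=True)

    w, v = np.linalg.eig(r)
    i = int(np.argmin(np.abs(w - 1.0)))
    axis = np.real(v[:, i])
    axis = axis / np.linalg.norm(axis)
    k = int(np.argmax(np.abs(axis)))
    if axis[k] < 0:
        axis = -axis
    return RotationAxis(axis, angle, degenerate=False)


def axis_misalignment(u, v) -> float:
    """Angle in degrees between two rotation axes, sign-blind, in [0, 90].

    The cosine of the angle comes straight from the dot product of the
    unit axes; taking its absolute value resolves the inherent eigenvector
    sign ambiguity.  Accepts raw unit vectors or :class:`RotationAxis`
    results; a degenerate axis (identity rotation) contributes zero
    misalignment with a warning, since an identity registration of an
    identity ground truth is a perfect result, not an error.
    """
    vecs = []
    for a in (u, v):
        if isinstance(a, RotationAxis):
            if a.degenerate:
                warnings.warn(
                    "rotation axis undefined (angle ~ 0); reporting 0 deg misalignment",
                    stacklevel=2,
                )
                return 0.0
            vecs.append(a.vector)
        else:
            a = _as_point(a)
            n = np.linalg.norm(a)
            if n < 1e-12:
                raise ValueError("zero-length axis vector")
            vecs.append(a / n)
    c = np.clip(abs(float(np.dot(vecs[0], vecs[1]))), 0.0, 1.0)
    return float(np.degrees(np.arccos(c)))


def half_voxel_check(errors, voxel) -> np.ndarray:
    """Per-axis half-voxel tolerance: axis i passes iff |error_i| <= voxel_i / 2.

    The boundary is inclusive: an error of exactly half a voxel passes.
    """
    errors = _as_point(errors)
    voxel = _as_point(voxel)
    if np.any(voxel <= 0):
        raise ValueError(f"voxel dimensions must be positive, got {voxel}")
    return np.abs(errors) <= voxel / 2.0
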