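"""Structure-volume and Dice similarity scoring for contour propagation QA.

Deformably propagated contours are compared to contours drawn directly on
the target image via the Dice similarity coefficient

    DSC = 2 |A ∩ B| / (|A| + |B|)

computed either from binary masks on a shared grid or from the three
volumes (deformed, target, common) that any planning system can report.
Volumes are in cubic centimetres, the unit clinical systems print.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import GeometryError, UndefinedMetricError

__all__ = [
    "MaskVolume",
    "StructureComparison",
    "volume",
    "dice_from_volumes",
    "dice_from_masks",
    "direction_consistency",
    "dsc_tolerance_check",
]

MM3_PER_CC = 1000.0


@dataclass
class MaskVolume:
    """Binary occupancy volume on a regular axis-aligned grid.

    ``data`` is indexed ``[i, j, k]`` along the LPS x, y, z axes; the
    centre of voxel ``(i, j, k)`` sits at ``origin + index * spacing``
    (mm).  Direction cosines beyond the identity are not supported.
    """

    origin: np.ndarray
    spacing: np.ndarray
    data: np.ndarray
    name: str = ""

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3:
            raise GeometryError(f"mask must be 3-D, got {self.data.ndim}-D")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "MaskVolume", atol: float = 1e-6) -> bool:
        return (self.dims == other.dims
                and np.allclose(self.origin, other.origin, atol=atol)
                and np.allclose(self.spacing, other.spacing, atol=atol))


@dataclass
class StructureComparison:
    """Per-structure contour comparison record (volumes in cc)."""

    name: str
    volume_deformed: float
    volume_target: float
    common_volume: float
    dsc: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        if self.dsc is None:
            self.dsc = dice_from_volumes(
                self.volume_deformed, self.volume_target, self.common_volume
            )


def volume(mask: MaskVolume) -> float:
    """Structure volume in cc: occupied-voxel count times voxel volume."""
    return float(np.count_nonzero(mask.data)) * mask.voxel_volume_mm3 / MM3_PER_CC


def dice_from_volumes(va: float, vb: float, vab: float) -> float:
    """Dice coefficient from the deformed, target and common volumes.

    This is the hand-calculation path: the three volumes can be read off
    any planning system, no voxel data needed.  Two empty structures have
    no defined overlap ratio and raise rather than returning 0.
    """
    va, vb, vab = float(va), float(vb), float(vab)
    if va < 0 or vb < 0 or vab < 0:
        raise ValueError(f"volumes must be non-negative, got ({va}, {vb}, {vab})")
    if vab > min(va, vb) + 1e-9:
        raise ValueError(
            f"common volume {vab} exceeds the smaller structure volume {min(va, vb)}"
        )
    if va + vb == 0:
        raise UndefinedMetricError("DSC undefined: both structures are empty")
    return 2.0 * vab / (va + vb)


def dice_from_masks(a: MaskVolume, b: MaskVolume) -> StructureComparison:
    """Voxelwise Dice between a deformed mask ``a`` and a target mask ``b``.

    The masks must live on an identical grid; no implicit resampling is
    performed (resampling policy would silently change the DSC).
    """
    if not a.same_grid(b):
        raise GeometryError(
            "masks are on different grids "
            f"(dims {a.dims} vs {b.dims}, origin {a.origin} vs {b.origin}, "
            f"spacing {a.spacing} vs {b.spacing}); resample upstream"
        )
    vox_cc = a.voxel_volume_mm3 / MM3_PER_CC
    va = float(np.count_nonzero(a.data)) * vox_cc
    vb = float(np.count_nonzero(b.data)) * vox_cc
    vab = float(np.count_nonzero(a.data & b.data)) * vox_cc
    name = a.name or b.name
    return StructureComparison(name, va, vb, vab)


def direction_consistency(fwd, bwd):
    """Per-structure DSC change between forward and reverse registrations.

    Returns ``(deltas, max_abs_delta)`` where ``deltas`` maps structure
    name to ``dsc_forward - dsc_backward``.  Structures present in only
    one list are excluded with a warning.
    """
    f = {c.name: c.dsc for c in fwd}
    b = {c.name: c.dsc for c in bwd}
    unmatched = sorted(set(f) ^ set(b))
    if unmatched:
        warnings.warn(f"structures without a counterpart excluded: {unmatched}", stacklevel=2)
    common = [n for n in f if n in b]
    deltas = {n: f[n] - b[n] for n in common}
    max_abs = max((abs(d) for d in deltas.values()), default=0.0)
    return deltas, max_abs


def dsc_tolerance_check(dsc: float, acceptable: float = 0.8, good: float = 0.9) -> str:
    """Band label for a DSC value against the recommended 0.8–0.9 range.

    Returns ``"fail"`` below ``acceptable``, ``"acceptable"`` within the
    band, ``"good"`` above it.
    """
    if not 0.0 <= dsc <= 1.0:
        raise ValueError(f"DSC must be in [0, 1], got {dsc}")
    if not 0 < acceptable <= good:
        raise ValueError("band edges must satisfy 0 < acceptable <= good")
    if dsc < acceptable:
        return "fail"
    if dsc <= good:
        return "acceptable"
    return "good"
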