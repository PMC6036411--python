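"""Deformation vector fields and the point-mapping chain of a deformable registration.

A deformable spatial registration stores a dense grid of per-voxel
displacement vectors (the "Vector Grid Data"), optionally sandwiched
between pre- and post-displacement rigid transforms.  Mapping a point p
from the target frame into the moving frame is

    q = post( pre(p) + d(pre(p)) )

where d(.) is the displacement field sampled at the (pre-transformed)
point.  The field is stored at voxel centres; between centres we
interpolate trilinearly, which reproduces componentwise-affine fields
exactly and is accurate to second order otherwise.  DVF grids are often
coarser than the images they register (vendors downsample by 2x or 4x),
so the grid carries its own geometry and is never inferred from images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
from scipy.interpolate import RegularGridInterpolator

from .exceptions import GeometryError, OutOfGridError
from .transforms import HomogeneousTransform

__all__ = ["DVFGrid", "DeformableRegRecord", "sample_dvf", "apply_deformable"]


@dataclass
class DVFGrid:
    """Regular grid of displacement vectors (mm) in DICOM LPS.

    ``displacements`` has shape ``(ni, nj, nk, 3)``; element ``[i, j, k]``
    is the displacement of the voxel centre at ``origin + (i,j,k)*spacing``.
    By the direction contract of this package the field maps points of the
    target frame to the moving frame.
    """

    origin: np.ndarray
    spacing: np.ndarray
    displacements: np.ndarray

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)
        self.spacing = np.asarray(self.spacing, dtype=float).reshape(3)
        if np.any(self.spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {self.spacing}")
        d = np.asarray(self.displacements, dtype=float)
        if d.ndim != 4 or d.shape[3] != 3:
            raise GeometryError(
                f"displacements must have shape (ni, nj, nk, 3), got {d.shape}"
            )
        if not np.all(np.isfinite(d)):
            raise GeometryError("displacement field contains non-finite values")
        self.displacements = d

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.displacements.shape[:3]

    @property
    def hull(self) -> tuple[np.ndarray, np.ndarray]:
        """(lower, upper) corners of the voxel-centre bounding box, mm."""
        lo = self.origin
        hi = self.origin + (np.array(self.dims) - 1) * self.spacing
        return lo, hi

    def contains(self, points, atol: float = 1e-9) -> np.ndarray:
        lo, hi = self.hull
        p = np.atleast_2d(np.asarray(points, dtype=float))
        return np.all((p >= lo - atol) & (p <= hi + atol), axis=1)


@dataclass
class DeformableRegRecord:
    """A deformable registration: DVF plus optional pre/post rigid transforms."""

    dvf: DVFGrid
    pre_rigid: Optional[HomogeneousTransform] = None
    post_rigid: Optional[HomogeneousTransform] = None
    provenance: dict = field(default_factory=dict)


def _interpolator(grid: DVFGrid, method: str) -> RegularGridInterpolator:
    axes = tuple(
        grid.origin[a] + np.arange(grid.dims[a]) * grid.spacing[a] for a in range(3)
    )
    return RegularGridInterpolator(axes, grid.displacements, method=method,
                                   bounds_error=False, fill_value=None)


def sample_dvf(grid: DVFGrid, points,
               policy: Literal["strict", "clamp"] = "strict",
               method: Literal["linear", "nearest"] = "linear") -> np.ndarray:
    """Interpolate the displacement field at one point or an (n,3) array.

    Trilinear by default; exact at voxel centres and for componentwise
    affine fields.  Points outside the voxel-centre hull raise
    :class:`OutOfGridError` under the default strict policy; under
    ``policy="clamp"`` they are clamped to the hull boundary (never
    extrapolated) with a warning.
    """
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    if p2.shape[1] != 3:
        raise ValueError(f"points must be 3-vectors, got shape {p.shape}")

    inside = grid.contains(p2)
    if not np.all(inside):
        idx = np.nonzero(~inside)[0]
        if policy == "strict":
            raise OutOfGridError(
                idx.tolist(),
                f"{idx.size} point(s) outside the DVF hull {grid.hull}: indices {idx.tolist()[:10]}",
            )
        warnings.warn(f"{idx.size} point(s) clamped to the DVF hull", stacklevel=2)
        lo, hi = grid.hull
        p2 = np.clip(p2, lo, hi)

    # single-voxel axes cannot be linearly interpolated; snap to the plane
    dims = np.array(grid.dims)
    if np.any(dims == 1):
        p2 = p2.copy()
        for a in np.nonzero(dims == 1)[0]:
            p2[:, a] = grid.origin[a]
        sub = tuple(slice(None) if n > 1 else 0 for n in dims)
        axes = tuple(
            grid.origin[a] + np.arange(grid.dims[a]) * grid.spacing[a]
            for a in range(3) if dims[a] > 1
        )
        vals = grid.displacements[sub]
        if not axes:  # 1x1x1 grid
            out = np.broadcast_to(vals.reshape(3), (p2.shape[0], 3)).copy()
            return out[0] if single else out
        rgi = RegularGridInterpolator(axes, vals, method=method)
        q = p2[:, [a for a in range(3) if dims[a] > 1]]
        out = rgi(q)
        return out[0] if single else out

    out = _interpolator(grid, method)(np.clip(p2, *grid.hull))
    return out[0] if single else out


def apply_deformable(rec: DeformableRegRecord, points,
                     policy: Literal["strict", "clamp"] = "strict",
                     method: Literal["linear", "nearest"] = "linear") -> np.ndarray:
    """Map point(s) through the full pre-rigid → displacement → post-rigid chain."""
    p = np.asarray(points, dtype=float)
    single = p.ndim == 1
    p2 = np.atleast_2d(p)
    if rec.pre_rigid is not None:
        p2 = rec.pre_rigid.apply(p2)
    q = p2 + sample_dvf(rec.dvf, p2, policy=policy, method=method)
    if rec.post_rigid is not None:
        q = rec.post_rigid.apply(q)
    return q[0] if single else q
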