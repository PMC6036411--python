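"""Seeded synthetic fixtures with exact ground truth for every QA pathway.

The public validation datasets these tests are normally run against (rigid
phantom shifts/rotations, thoracic landmark sets, expert contour pairs)
require downloads and licences.  This module replaces them with generated
stand-ins that carry *exact* analytic ground truth, so every metric in the
toolkit can be verified end-to-end offline:

* rigid cases — a nominal transform built from a known patient shift and
  rotation, written out as a registration object with an optionally
  injected, exactly-known error;
* deformable cases — displacement fields from analytic families (affine,
  gaussian bump, sinusoid) sampled onto a DVF grid, plus landmark pairs
  whose mapped positions come from the analytic field, with a conservative
  trilinear interpolation-error bound in the manifest;
* contour cases — rasterized sphere/box mask pairs with closed-form
  volumes, overlap and Dice.

Each generator is a pure function of its seed: identical seeds reproduce
identical bundles.  Manifests record every expected value a test needs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.transform import Rotation as ScipyRotation

from . import dicom_io
from .contours import MaskVolume, dice_from_volumes
from .dvf import DeformableRegRecord, DVFGrid
from .transforms import (
    Direction,
    HomogeneousTransform,
    PatientShift,
    RotationSpec,
    ShiftedRole,
    build_nominal_transform,
    invert_transform,
    rotation_axis,
)

__all__ = ["FixtureBundle", "gen_rigid_case", "gen_dvf_case", "gen_mask_pair"]

# The default rigid scenario mirrors the rotation+translation phantom case:
# moving dataset shifted 5 mm Lt, 15 mm Ant, 20 mm Sup relative to the
# stationary one, rotated -5 deg about x, 8 about y, 10 about z.
DEFAULT_SHIFT = (((5.0, "Lt"), (15.0, "Ant"), (20.0, "Sup")), ShiftedRole.STATIONARY)
DEFAULT_ROTATION = (-5.0, 8.0, 10.0)


@dataclass
class FixtureBundle:
    """A generated QA scenario: in-memory objects, optional files, ground truth."""

    seed: int
    kind: str
    manifest: dict
    objects: dict = field(default_factory=dict)
    files: dict = field(default_factory=dict)


def _tilted_axis_rotation(axis: np.ndarray, angle_deg: float,
                          tilt_deg: float, rng: np.random.Generator) -> np.ndarray:
    """Rotation with the same angle but axis tilted by exactly ``tilt_deg``."""
    axis = axis / np.linalg.norm(axis)
    # a seeded direction perpendicular to the axis
    v = rng.normal(size=3)
    v -= axis * (v @ axis)
    while np.linalg.norm(v) < 1e-9:  # pragma: no cover - measure-zero retry
        v = rng.normal(size=3)
        v -= axis * (v @ axis)
    v /= np.linalg.norm(v)
    tilt = ScipyRotation.from_rotvec(np.deg2rad(tilt_deg) * v)
    new_axis = tilt.apply(axis)
    return ScipyRotation.from_rotvec(np.deg2rad(angle_deg) * new_axis).as_matrix()


def gen_rigid_case(seed: int,
                   shift: Optional[PatientShift] = None,
                   rotation: Optional[RotationSpec] = None,
                   injected_translation_error=(0.0, 0.0, 0.0),
                   injected_axis_tilt_deg: float = 0.0,
                   out_dir=None) -> FixtureBundle:
    """Rigid QA scenario: nominal transform plus a 'reported' registration.

    The reported transform equals the inverted nominal transform
    (target-to-moving, what registration software exports) with the given
    errors injected: a per-axis translation offset, and/or a tilt of the
    rotation axis by exactly ``injected_axis_tilt_deg`` degrees (rotation
    angle preserved).  The manifest records the known translation, the
    injected errors and the expected axis misalignment, all of which the
    QA pipeline must recover.
    """
    rng = np.random.default_rng(seed)
    if shift is None:
        shift = PatientShift(*DEFAULT_SHIFT)
    if rotation is None:
        rotation = RotationSpec(*DEFAULT_ROTATION)

    nominal = build_nominal_transform(rotation, shift)
    perfect = invert_transform(nominal)  # target -> moving, like the DICOM object
    delta = np.asarray(injected_translation_error, dtype=float).reshape(3)

    rep_rot = perfect.rotation
    nominal_axis = rotation_axis(perfect.rotation)
    if injected_axis_tilt_deg != 0.0:
        if nominal_axis.degenerate:
            raise ValueError("cannot tilt the rotation axis of an identity rotation")
        rep_rot = _tilted_axis_rotation(
            nominal_axis.vector, nominal_axis.angle_deg, injected_axis_tilt_deg, rng
        )
    reported = HomogeneousTransform(rep_rot, perfect.translation + delta,
                                    Direction.TARGET_TO_MOVING)

    manifest = {
        "seed": int(seed),
        "shift_components": [list(c) for c in shift.components],
        "shifted_role": shift.shifted_role.value if shift.shifted_role else None,
        "rotation_deg": [rotation.angle_x, rotation.angle_y, rotation.angle_z],
        "known_T_mm": perfect.translation.tolist(),
        "expected_translation_errors_mm": delta.tolist(),
        "expected_axis_misalignment_deg": float(injected_axis_tilt_deg),
        "nominal_axis": None if nominal_axis.degenerate else nominal_axis.vector.tolist(),
        "nominal_rotation_angle_deg": nominal_axis.angle_deg,
    }
    objects = {"nominal": nominal, "perfect": perfect, "reported": reported}
    files = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files["reported_reg"] = dicom_io.write_rigid_reg(
            reported, out_dir / "reported_reg.dcm",
            uid_entropy=f"regqa-rigid-{seed}",
        )
        _write_manifest(manifest, out_dir / "manifest.json")
        files["manifest"] = out_dir / "manifest.json"
    return FixtureBundle(seed, "rigid", manifest, objects, files)


# -- analytic displacement-field families -----------------------------------

def _affine_field(rng: np.random.Generator, params: dict):
    a = params.get("A")
    b = params.get("b")
    if a is None:
        a = rng.uniform(-0.03, 0.03, size=(3, 3))
    if b is None:
        b = rng.uniform(-3.0, 3.0, size=3)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)

    def d(p):
        return np.atleast_2d(p) @ a.T + b

    return d, {"A": a.tolist(), "b": b.tolist()}, 0.0


def _gaussian_bump_field(params: dict, grid_extent):
    amp = np.asarray(params.get("amplitude", (8.0, 8.0, 8.0)), dtype=float) * np.ones(3)
    sigma = float(params.get("sigma", 30.0))
    centre = np.asarray(params.get("centre", (np.asarray(grid_extent[0]) + np.asarray(grid_extent[1])) / 2.0), dtype=float)

    def d(p):
        p = np.atleast_2d(p)
        r2 = np.sum((p - centre) ** 2, axis=1, keepdims=True)
        return amp * np.exp(-r2 / (2.0 * sigma**2))

    # max |d2/dxi2| of A*exp(-r^2/2s^2) along any axis is A/s^2
    m2 = float(np.max(np.abs(amp))) / sigma**2
    return d, {"amplitude": amp.tolist(), "sigma": sigma, "centre": centre.tolist()}, m2


def _sinusoid_field(params: dict):
    amp = np.asarray(params.get("amplitude", (3.0, 3.0, 3.0)), dtype=float) * np.ones(3)
    wavelength = float(params.get("wavelength", 60.0))
    k = 2.0 * np.pi / wavelength

    def d(p):
        p = np.atleast_2d(p)
        # component i depends on coordinate i only: keeps the bound simple
        return amp * np.sin(k * p)

    m2 = float(np.max(np.abs(amp))) * k**2
    return d, {"amplitude": amp.tolist(), "wavelength": wavelength}, m2


def gen_dvf_case(seed: int,
                 family: str = "affine",
                 params: Optional[dict] = None,
                 origin=(-40.0, -40.0, -30.0),
                 spacing=(2.0, 2.0, 5.0),
                 dims=(41, 41, 13),
                 n_landmarks: int = 100,
                 out_dir=None) -> FixtureBundle:
    """Deformable QA scenario: analytic field on a DVF grid plus landmark pairs.

    The grid defaults mimic a vendor-exported field: ~2 mm in-plane and
    5 mm slice spacing (vendor DVFs are downsampled relative to the
    images).  Landmarks are drawn uniformly inside the voxel-centre hull
    with a one-voxel margin; their moving-frame positions come from the
    analytic field, so any discrepancy seen by the TRE pipeline is pure
    interpolation error, bounded in the manifest by

        bound = sqrt(3)/8 * sum_i h_i^2 * max|d''|        (0 for affine)

    the standard worst-case bound for componentwise trilinear
    interpolation of a field with bounded second derivatives.
    """
    rng = np.random.default_rng(seed)
    params = dict(params or {})
    origin = np.asarray(origin, dtype=float)
    spacing = np.asarray(spacing, dtype=float)
    dims = tuple(int(n) for n in dims)
    hull_hi = origin + (np.array(dims) - 1) * spacing

    if family == "affine":
        d, fam_params, m2 = _affine_field(rng, params)
        bound = 1e-5  # exact up to float round-off
    elif family == "gaussian_bump":
        d, fam_params, m2 = _gaussian_bump_field(params, (origin, hull_hi))
        bound = np.sqrt(3.0) / 8.0 * float(np.sum(spacing**2)) * m2
    elif family == "sinusoid":
        d, fam_params, m2 = _sinusoid_field(params)
        bound = np.sqrt(3.0) / 8.0 * float(np.sum(spacing**2)) * m2
    else:
        raise ValueError(f"unknown field family {family!r}")

    axes = [origin[a] + np.arange(dims[a]) * spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    centres = np.column_stack([xx.ravel(), yy.ravel(), zz.ravel()])
    disp = d(centres).reshape(dims + (3,))
    grid = DVFGrid(origin, spacing, disp)
    rec = DeformableRegRecord(grid)

    lo = origin + spacing
    hi = hull_hi - spacing
    fixed = rng.uniform(lo, hi, size=(int(n_landmarks), 3))
    moving = fixed + d(fixed)

    manifest = {
        "seed": int(seed),
        "family": family,
        "field_params": fam_params,
        "origin_mm": origin.tolist(),
        "spacing_mm": spacing.tolist(),
        "dims": list(dims),
        "n_landmarks": int(n_landmarks),
        "interpolation_bound_mm": float(bound),
        "bound_formula": "sqrt(3)/8 * sum(spacing^2) * max|second derivative|",
    }
    objects = {"record": rec, "field": d, "fixed": fixed, "moving": moving}
    files = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files["deformable_reg"] = dicom_io.write_deformable_reg(
            rec, out_dir / "deformable_reg.dcm", uid_entropy=f"regqa-dvf-{seed}"
        )
        files["landmarks_fixed"] = dicom_io.write_landmarks(
            fixed, out_dir / "landmarks_fixed.txt"
        )
        files["landmarks_moving"] = dicom_io.write_landmarks(
            moving, out_dir / "landmarks_moving.txt"
        )
        _write_manifest(manifest, out_dir / "manifest.json")
        files["manifest"] = out_dir / "manifest.json"
    return FixtureBundle(seed, "dvf", manifest, objects, files)


# -- mask pairs --------------------------------------------------------------

def _sphere_lens_volume(r: float, d: float) -> float:
    """Overlap volume of two equal spheres of radius r with centres d apart."""
    if d >= 2.0 * r:
        return 0.0
    return np.pi * (4.0 * r + d) * (2.0 * r - d) ** 2 / 12.0


def _rasterize(predicate, origin, spacing, dims) -> np.ndarray:
    axes = [origin[a] + np.arange(dims[a]) * spacing[a] for a in range(3)]
    xx, yy, zz = np.meshgrid(*axes, indexing="ij")
    return predicate(xx, yy, zz)


def gen_mask_pair(seed: int,
                  shape: str = "spheres",
                  radius: float = 1.0,
                  separation: float = 1.0,
                  halfwidths=(0.5, 0.5, 0.5),
                  overlap_fraction: float = 0.5,
                  voxel: float = 0.02,
                  out_dir=None) -> FixtureBundle:
    """Rasterized mask pair with closed-form volumes, overlap and Dice.

    ``spheres``: two equal spheres of ``radius`` with centres ``separation``
    apart along x; the overlap is the lens volume
    pi (4r + d)(2r - d)^2 / 12, so for unit spheres one radius apart the
    exact Dice is 5/16 = 0.3125.  Voxel centres inside the surface count
    as occupied; the manifest states a conservative voxelization tolerance
    proportional to the voxel size.

    ``boxes``: two axis-aligned boxes of the given half-widths offset
    along x so a fraction ``overlap_fraction`` of their width overlaps;
    when the voxel size is commensurate with all box edges the
    rasterization (voxel centres, half-open convention) is exact.
    """
    voxel = float(voxel)
    spacing = np.array([voxel] * 3)
    if shape == "spheres":
        r, dsep = float(radius), float(separation)
        c1 = np.array([0.0, 0.0, 0.0])
        c2 = np.array([dsep, 0.0, 0.0])
        pad = 2.0 * voxel
        lo = np.minimum(c1, c2) - r - pad
        hi = np.maximum(c1, c2) + r + pad
        # half-voxel offset so no voxel centre sits exactly on the surface
        origin = lo + voxel / 2.0
        dims = tuple(int(np.ceil((hi[a] - origin[a]) / voxel)) + 1 for a in range(3))

        def inside(c):
            return lambda x, y, z: (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2 < r**2

        a = MaskVolume(origin, spacing, _rasterize(inside(c1), origin, spacing, dims), "sphere_deformed")
        b = MaskVolume(origin, spacing, _rasterize(inside(c2), origin, spacing, dims), "sphere_target")
        v = 4.0 / 3.0 * np.pi * r**3 / 1000.0
        vab = _sphere_lens_volume(r, dsep) / 1000.0
        dsc = dice_from_volumes(v, v, vab)
        tol = {"volume_rel": 3.0 * voxel / r, "dsc_abs": voxel / r}
    elif shape == "boxes":
        hw = np.asarray(halfwidths, dtype=float)
        width = 2.0 * hw[0]
        offset = width * (1.0 - float(overlap_fraction))
        c1 = np.zeros(3)
        c2 = np.array([offset, 0.0, 0.0])
        pad = 2.0 * voxel
        origin = c1 - hw - pad + voxel / 2.0
        hi = c2 + hw + pad
        dims = tuple(int(np.ceil((hi[a] - origin[a]) / voxel)) + 1 for a in range(3))

        def inside(c):
            # half-open [lo, hi) keeps shared faces from double counting
            return lambda x, y, z: (
                (x >= c[0] - hw[0]) & (x < c[0] + hw[0])
                & (y >= c[1] - hw[1]) & (y < c[1] + hw[1])
                & (z >= c[2] - hw[2]) & (z < c[2] + hw[2])
            )

        a = MaskVolume(origin, spacing, _rasterize(inside(c1), origin, spacing, dims), "box_deformed")
        b = MaskVolume(origin, spacing, _rasterize(inside(c2), origin, spacing, dims), "box_target")
        v = float(np.prod(2.0 * hw)) / 1000.0
        vab = max(width - offset, 0.0) * 2.0 * hw[1] * 2.0 * hw[2] / 1000.0
        dsc = dice_from_volumes(v, v, vab)
        tol = {"volume_rel": 0.0, "dsc_abs": 0.0}
    else:
        raise ValueError(f"unknown shape {shape!r}")

    manifest = {
        "seed": int(seed),
        "shape": shape,
        "voxel_mm": voxel,
        "expected_volume_a_cc": v,
        "expected_volume_b_cc": v,
        "expected_common_cc": vab,
        "expected_dsc": dsc,
        "tolerance": tol,
    }
    objects = {"mask_deformed": a, "mask_target": b}
    files = {}
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        files["mask_deformed"] = dicom_io.write_mask(a, out_dir / "mask_deformed.nrrd")
        files["mask_target"] = dicom_io.write_mask(b, out_dir / "mask_target.nrrd")
        _write_manifest(manifest, out_dir / "manifest.json")
        files["manifest"] = out_dir / "manifest.json"
    return FixtureBundle(seed, "mask", manifest, objects, files)


def _write_manifest(manifest: dict, path: Path) -> None:
    import json

    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
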