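"""Pass/fail QA report assembly around the metric modules.

Each ``run_*`` entry point takes a declarative config (a plain dict,
typically loaded from YAML/JSON by the CLI), executes one QA test
end-to-end — parse inputs, compute metrics, apply tolerances — and
returns a :class:`QAReport` that serializes to JSON or CSV.  Every
verdict stored in a report can be recomputed from the metrics stored
alongside it; thresholds are recorded explicitly so a report is
self-contained.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import numpy as np
import pandas as pd

from . import dicom_io
from .contours import dice_from_masks, dsc_tolerance_check
from .transforms import (
    PatientShift,
    RotationSpec,
    ShiftedRole,
    axis_misalignment,
    build_nominal_transform,
    half_voxel_check,
    invert_transform,
    rotation_axis,
    translation_errors,
)
from .tre import FiducialSet, compute_tre, tre_tolerance_check

__all__ = ["ToleranceSpec", "QAReport", "run_rigid_check", "run_tre", "run_dice"]


def _pkg_version() -> str:
    try:
        return version("regqa")
    except PackageNotFoundError:  # pragma: no cover - only when not installed
        return "unknown"


@dataclass(frozen=True)
class ToleranceSpec:
    """QA tolerances: half-voxel per axis, TRE mean/max, DSC bands."""

    half_voxel_mm: tuple | None = None  # full voxel dims; check uses half
    tre_mean_mm: float = 2.0
    tre_max_mm: float = 5.0
    dsc_acceptable: float = 0.8
    dsc_good: float = 0.9

    def __post_init__(self):
        if self.tre_mean_mm <= 0 or self.tre_max_mm <= 0:
            raise ValueError("TRE tolerances must be positive")
        if not 0 < self.dsc_acceptable <= self.dsc_good <= 1:
            raise ValueError("DSC band edges must satisfy 0 < acceptable <= good <= 1")
        if self.half_voxel_mm is not None:
            v = tuple(float(x) for x in self.half_voxel_mm)
            if len(v) != 3 or any(x <= 0 for x in v):
                raise ValueError("voxel dims must be three positive numbers")
            object.__setattr__(self, "half_voxel_mm", v)


@dataclass
class QAReport:
    """One QA test result: provenance, metrics (with units), verdicts."""

    case_id: str
    kind: str
    inputs: dict = field(default_factory=dict)
    tolerances: dict = field(default_factory=dict)
    metrics: dict = field(default_factory=dict)
    verdicts: dict = field(default_factory=dict)
    tables: dict = field(default_factory=dict)  # name -> DataFrame
    version: str = field(default_factory=_pkg_version)

    def to_dict(self) -> dict:
        d = {k: _jsonable(v) for k, v in dataclasses.asdict(self).items() if k != "tables"}
        d["tables"] = {name: df.to_dict(orient="records") for name, df in self.tables.items()}
        return d

    def to_json(self, path=None, **kwargs) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)
        if path is not None:
            Path(path).write_text(s + "\n")
        return s

    def to_csv(self, path) -> None:
        """Flat metric/verdict rows; per-point tables go to sibling files."""
        rows = [{"case_id": self.case_id, "field": f"metric.{k}", "value": _scalarize(v)}
                for k, v in sorted(self.metrics.items())]
        rows += [{"case_id": self.case_id, "field": f"verdict.{k}", "value": _scalarize(v)}
                 for k, v in sorted(self.verdicts.items())]
        path = Path(path)
        pd.DataFrame(rows).to_csv(path, index=False)
        for name, df in self.tables.items():
            df.to_csv(path.with_name(f"{path.stem}_{name}.csv"), index=False)


def _jsonable(v):
    if isinstance(v, np.ndarray):
        return v.tolist()
    if isinstance(v, (np.floating, np.integer)):
        return v.item()
    if isinstance(v, dict):
        return {k: _jsonable(x) for k, x in v.items()}
    if isinstance(v, (list, tuple)):
        return [_jsonable(x) for x in v]
    return v


def _scalarize(v):
    v = _jsonable(v)
    return json.dumps(v) if isinstance(v, (list, dict)) else v


def _shift_from_config(cfg: dict) -> PatientShift:
    role = cfg.get("shifted_role", "stationary_is_shifted")
    return PatientShift(
        tuple((float(m), str(d)) for m, d in cfg["components"]),
        ShiftedRole(role),
    )


def _rotation_from_config(cfg: dict | None) -> RotationSpec:
    cfg = cfg or {}
    return RotationSpec(
        float(cfg.get("x", 0.0)), float(cfg.get("y", 0.0)), float(cfg.get("z", 0.0))
    )


def run_rigid_check(config: dict) -> QAReport:
    """Score a rigid registration object against known shifts/rotations.

    Config keys: ``reg_file``; ``shift`` (``components`` as
    ``[[magnitude, direction], ...]`` plus ``shifted_role``); optional
    ``rotation`` (degrees about x/y/z); ``voxel_mm`` for the half-voxel
    verdict; optional ``case_id``, ``select``, ``report_point``.
    """
    rec = dicom_io.read_rigid_reg(config["reg_file"], select=config.get("select"))
    shift = _shift_from_config(config["shift"])
    rotation = _rotation_from_config(config.get("rotation"))
    has_rotation = any((rotation.angle_x, rotation.angle_y, rotation.angle_z))

    nominal = build_nominal_transform(rotation, shift)
    expected = invert_transform(nominal)  # target -> moving, as reported by software
    errors = translation_errors(rec.transform, expected.translation)

    tol = ToleranceSpec(half_voxel_mm=tuple(config["voxel_mm"]) if "voxel_mm" in config else None)
    metrics = {
        "known_T_mm": expected.translation,
        "reported_T_mm": rec.transform.translation,
        "translation_errors_mm": errors,
    }
    verdicts = {}
    if tol.half_voxel_mm is not None:
        passes = half_voxel_check(errors, tol.half_voxel_mm)
        verdicts["half_voxel_pass_xyz"] = [bool(p) for p in passes]
        verdicts["half_voxel_pass"] = bool(np.all(passes))
    if has_rotation:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nominal_axis = rotation_axis(expected.rotation)
            reported_axis = rotation_axis(rec.transform.rotation)
            metrics["axis_misalignment_deg"] = axis_misalignment(nominal_axis, reported_axis)
        metrics["nominal_axis"] = nominal_axis.vector
        metrics["reported_axis"] = reported_axis.vector
        metrics["axis_degenerate"] = nominal_axis.degenerate or reported_axis.degenerate

    return QAReport(
        case_id=str(config.get("case_id", "rigid")),
        kind="rigid_check",
        inputs={"reg_file": str(config["reg_file"]), "parse_mode": rec.parse_mode,
                "shift": config["shift"], "rotation": config.get("rotation")},
        tolerances=dataclasses.asdict(tol),
        metrics=metrics,
        verdicts=verdicts,
    )


def run_tre(config: dict) -> QAReport:
    """Landmark TRE of a deformable (or rigid) registration.

    Config keys: ``reg_file`` (deformable object) or ``rigid_reg_file``;
    ``landmarks_fixed`` / ``landmarks_moving``; ``dialect`` (``mm`` or
    ``voxel_index`` with ``index_base``/``origin``/``spacing``); optional
    ``sd_ddof``, ``tre_mean_mm``, ``tre_max_mm``, ``skip_out_of_grid``.
    """
    dialect = config.get("dialect", "mm")
    lm_kwargs = dict(
        dialect=dialect,
        index_base=int(config.get("index_base", 0)),
        origin=config.get("origin"),
        spacing=config.get("spacing"),
    )
    fixed = dicom_io.read_landmarks(config["landmarks_fixed"], **lm_kwargs)
    moving = dicom_io.read_landmarks(config["landmarks_moving"], **lm_kwargs)
    fset = FiducialSet(fixed.points, moving.points)

    if "reg_file" in config:
        mapping = dicom_io.read_deformable_reg(config["reg_file"])
        reg_input = str(config["reg_file"])
    elif "rigid_reg_file" in config:
        mapping = dicom_io.read_rigid_reg(config["rigid_reg_file"]).transform
        reg_input = str(config["rigid_reg_file"])
    else:
        raise KeyError("config needs reg_file (deformable) or rigid_reg_file")

    stats = compute_tre(fset, mapping, sd_ddof=int(config.get("sd_ddof", 1)),
                        skip_out_of_grid=bool(config.get("skip_out_of_grid", False)))
    tol = ToleranceSpec(tre_mean_mm=float(config.get("tre_mean_mm", 2.0)),
                        tre_max_mm=float(config.get("tre_max_mm", 5.0)))
    check = tre_tolerance_check(stats, tol.tre_mean_mm, tol.tre_max_mm)
    return QAReport(
        case_id=str(config.get("case_id", "tre")),
        kind="tre",
        inputs={"reg_file": reg_input, "dialect": dialect,
                "landmarks_fixed": str(config["landmarks_fixed"]),
                "landmarks_moving": str(config["landmarks_moving"]),
                "n_landmarks": stats.n},
        tolerances=dataclasses.asdict(tol),
        metrics={"mean_tre_mm": stats.mean, "sd_tre_mm": stats.sd,
                 "max_tre_mm": stats.max, "n": stats.n,
                 "mean_axis_deltas_mm": stats.axis_deltas},
        verdicts={"tre_pass": check["pass"], "mean_pass": check["mean_pass"],
                  "max_pass": check["max_pass"]},
        tables={"per_point": stats.per_point_frame()},
    )


def run_dice(config: dict) -> QAReport:
    """Dice similarity of propagated vs target contours.

    Config keys: either ``deformed_mask``/``target_mask`` (single
    structure, optional ``name``) or ``pairs`` — a list of
    ``{name, deformed_mask, target_mask}`` entries.  Optional DSC band
    edges ``dsc_acceptable``/``dsc_good``.
    """
    pairs = config.get("pairs")
    if pairs is None:
        pairs = [{"name": config.get("name", ""),
                  "deformed_mask": config["deformed_mask"],
                  "target_mask": config["target_mask"]}]
    tol = ToleranceSpec(dsc_acceptable=float(config.get("dsc_acceptable", 0.8)),
                        dsc_good=float(config.get("dsc_good", 0.9)))
    rows, verdicts = [], {}
    for p in pairs:
        a = dicom_io.read_mask(p["deformed_mask"], name=p.get("name", ""))
        b = dicom_io.read_mask(p["target_mask"], name=p.get("name", ""))
        cmp_ = dice_from_masks(a, b)
        band = dsc_tolerance_check(cmp_.dsc, tol.dsc_acceptable, tol.dsc_good)
        rows.append({"ROI": cmp_.name, "DSC": round(cmp_.dsc, 3),
                     "volume_deformed_cc": cmp_.volume_deformed,
                     "volume_target_cc": cmp_.volume_target,
                     "common_volume_cc": cmp_.common_volume,
                     "band": band})
        verdicts[cmp_.name or "structure"] = band
    table = pd.DataFrame(rows)
    return QAReport(
        case_id=str(config.get("case_id", "dice")),
        kind="dice",
        inputs={"pairs": [{k: str(v) for k, v in p.items()} for p in pairs]},
        tolerances=dataclasses.asdict(tol),
        metrics={"mean_dsc": float(table["DSC"].mean()),
                 "min_dsc": float(table["DSC"].min())},
        verdicts=verdicts,
        tables={"per_structure": table},
    )
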