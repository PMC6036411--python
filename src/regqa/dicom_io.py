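"""Readers and writers for spatial registration objects, landmark lists and masks.

Rigid registrations live in DICOM Spatial Registration objects as a
16-value row-major 4x4 matrix; deformable registrations in Deformable
Spatial Registration objects as a binary Vector Grid Data stream of
per-voxel (dx, dy, dz) float32 triplets, optionally framed by pre/post
rigid matrices.  Both are read tag-based via pydicom when the file is
valid DICOM; for rigid objects a raw text scan is also provided, because
the matrix is visible in the binary file as an ASCII run of 16 separated
numbers ending "0/0/0/1" and extracting it with a text editor is a useful
manual cross-check.  Tag-based parsing is authoritative; the parse mode is
recorded in the returned record's provenance.

Landmark lists are delimited text with three numeric columns.  The dialect
(mm vs voxel index, 0- vs 1-based) must be declared by the caller — it is
never auto-detected, since a silent unit mix-up is exactly the failure
mode this toolkit exists to catch.

All coordinates are DICOM LPS mm; grids are axis-aligned
(point = origin + index * spacing) — direction cosines other than the
identity are rejected.
"""

from __future__ import annotations

import re
import warnings
from contextlib import contextmanager
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .contours import MaskVolume
from .dvf import DeformableRegRecord, DVFGrid
from .exceptions import AmbiguousMatrixError, GeometryError, ParseError
from .transforms import Direction, HomogeneousTransform, check_rotation

__all__ = [
    "RigidRegRecord",
    "LandmarkFile",
    "read_rigid_reg",
    "write_rigid_reg",
    "read_deformable_reg",
    "write_deformable_reg",
    "read_landmarks",
    "write_landmarks",
    "read_mask",
    "write_mask",
    "transform_to_string",
    "transform_from_string",
]

SPATIAL_REG_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.66.1"
DEFORMABLE_REG_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.66.3"

_NUM = r"[-+]?(?:\d+\.?\d*|\.\d+)(?:[eE][-+]?\d+)?"
_RUN_RE = re.compile(rf"{_NUM}(?:[/\\]{_NUM})+")


@dataclass
class RigidRegRecord:
    """A rigid registration read from file, with provenance."""

    transform: HomogeneousTransform
    source: str = ""
    parse_mode: str = "tag_based"  # or "raw_scan"
    frame_of_reference_uids: tuple = ()


@dataclass
class LandmarkFile:
    """Landmark coordinates converted to mm, with the declared dialect recorded."""

    points: np.ndarray
    dialect: str = "mm"  # or "voxel_index"
    index_base: int = 0
    source: str = ""

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)

    def __len__(self) -> int:
        return len(self.points)


# ---------------------------------------------------------------------------
# slash-string dialect

def transform_to_string(t: HomogeneousTransform, sep: str = "/") -> str:
    """Serialize row-major as 16 separated numbers, ending "0/0/0/1".

    Uses shortest-round-trip float formatting so the string re-parses to
    bit-identical values.
    """
    return sep.join(_fmt(v) for v in t.to_flat())


def _fmt(v: float) -> str:
    if v == int(v) and abs(v) < 1e15:
        return str(int(v))
    return repr(float(v))


def transform_from_string(s: str, direction: Direction = Direction.TARGET_TO_MOVING
                          ) -> HomogeneousTransform:
    """Parse a 16-value slash- (or backslash-) separated matrix string."""
    parts = [p for p in re.split(r"[/\\]", s.strip()) if p]
    if len(parts) != 16:
        raise ParseError(f"expected 16 values, got {len(parts)}")
    try:
        vals = [float(p) for p in parts]
    except ValueError as e:
        raise ParseError(f"non-numeric matrix entry: {e}") from None
    if vals[12:] != [0.0, 0.0, 0.0, 1.0]:
        raise ParseError(f"last four values must be 0/0/0/1, got {vals[12:]}")
    return HomogeneousTransform.from_flat(vals, direction)


# ---------------------------------------------------------------------------
# rigid registration objects

def _file_meta(sop_class: str, uid_entropy: Optional[str] = None) -> FileMetaDataset:
    fm = FileMetaDataset()
    fm.MediaStorageSOPClassUID = sop_class
    # entropy string makes the instance UID reproducible for seeded fixtures
    fm.MediaStorageSOPInstanceUID = generate_uid(
        entropy_srcs=[uid_entropy] if uid_entropy else None
    )
    fm.TransferSyntaxUID = ExplicitVRLittleEndian
    return fm


@contextmanager
def _quiet_ds():
    # shortest-repr DS values can exceed the 16-byte VR limit; exactness of
    # fixture round-trips is preferred, so silence the conformance warning
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*maximum length of 16.*")
        yield


def _matrix_item(t: HomogeneousTransform) -> Dataset:
    mat = Dataset()
    mat.FrameOfReferenceTransformationMatrixType = "RIGID"
    with _quiet_ds():
        mat.FrameOfReferenceTransformationMatrix = [_fmt(v) for v in t.to_flat()]
    return mat


def write_rigid_reg(t: HomogeneousTransform, path,
                    frame_of_reference_uid: Optional[str] = None,
                    description: str = "regqa fixture",
                    uid_entropy: Optional[str] = None) -> Path:
    """Write a minimal Spatial Registration object whose matrix re-reads exactly.

    Matrix values are stored as shortest-round-trip decimal strings; a few
    may exceed the 16-byte DS limit, which pydicom flags — exact recovery
    of the fixture transform is preferred over strict VR length here.
    """
    path = Path(path)
    ds = Dataset()
    ds.file_meta = _file_meta(SPATIAL_REG_SOP_CLASS, uid_entropy)
    ds.SOPClassUID = SPATIAL_REG_SOP_CLASS
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "REG"
    ds.ContentDescription = description
    for_uid = frame_of_reference_uid or generate_uid(
        entropy_srcs=[uid_entropy + "/frame"] if uid_entropy else None
    )
    ds.FrameOfReferenceUID = for_uid

    reg = Dataset()
    reg.FrameOfReferenceUID = for_uid
    mreg = Dataset()
    mreg.MatrixSequence = [_matrix_item(t)]
    reg.MatrixRegistrationSequence = [mreg]
    ds.RegistrationSequence = [reg]

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*maximum length of 16.*")
        ds.save_as(path, enforce_file_format=True)
    return path


def _scan_for_matrix(raw: bytes, select: Optional[int]) -> list[float]:
    text = raw.decode("latin-1", errors="replace")
    candidates = []
    for m in _RUN_RE.finditer(text):
        parts = re.split(r"[/\\]", m.group(0))
        if len(parts) < 16:
            continue
        try:
            vals = [float(p) for p in parts]
        except ValueError:
            continue
        tail = vals[-16:]
        if tail[12:] == [0.0, 0.0, 0.0, 1.0]:
            candidates.append(tail)
    if not candidates:
        raise ParseError("no 16-value matrix run ending 0/0/0/1 found")
    if len(candidates) > 1 and select is None:
        raise AmbiguousMatrixError(candidates)
    return candidates[select or 0]


def read_rigid_reg(path, select: Optional[int] = None,
                   direction: Direction = Direction.TARGET_TO_MOVING,
                   ortho_warn_tol: float = 1e-3) -> RigidRegRecord:
    """Read a rigid registration matrix from a Spatial Registration file.

    Tag-based parsing is attempted first; if the file is not valid DICOM
    (or lacks the registration sequences) the raw ASCII scan locates the
    matrix run instead.  The rotation block is checked for orthonormality
    and a warning is emitted above ``ortho_warn_tol`` deviation — file
    matrices are often rounded to few decimals.

    ``select`` picks one matrix when the raw scan finds several runs.
    """
    path = Path(path)
    vals = None
    mode = "tag_based"
    for_uids: tuple = ()
    try:
        ds = pydicom.dcmread(path)
        items = []
        for reg in ds.get("RegistrationSequence", []):
            for mreg in reg.get("MatrixRegistrationSequence", []):
                for mat in mreg.get("MatrixSequence", []):
                    items.append([float(v) for v in mat.FrameOfReferenceTransformationMatrix])
            if "FrameOfReferenceUID" in reg:
                for_uids = for_uids + (str(reg.FrameOfReferenceUID),)
        if not items:
            raise ParseError("no matrix sequence in DICOM dataset")
        if len(items) > 1 and select is None:
            raise AmbiguousMatrixError(items)
        vals = items[select or 0]
    except AmbiguousMatrixError:
        raise
    except Exception:
        mode = "raw_scan"
        vals = _scan_for_matrix(path.read_bytes(), select)

    if len(vals) != 16:
        raise ParseError(f"expected 16 matrix values, got {len(vals)}")
    if vals[12:] != [0.0, 0.0, 0.0, 1.0]:
        raise ParseError(f"matrix does not end in 0/0/0/1: {vals[12:]}")
    t = HomogeneousTransform.from_flat(vals, direction)
    check_rotation(t.rotation, atol=ortho_warn_tol, warn_only=True)
    return RigidRegRecord(t, source=str(path), parse_mode=mode,
                          frame_of_reference_uids=for_uids)


# ---------------------------------------------------------------------------
# deformable registration objects

def _flatten_dvf(d: np.ndarray) -> np.ndarray:
    # voxel order: i fastest, then j, then k  -> index = i + ni*(j + nj*k)
    return np.ascontiguousarray(d.transpose(2, 1, 0, 3), dtype="<f4").reshape(-1)


def _unflatten_dvf(flat: np.ndarray, dims) -> np.ndarray:
    ni, nj, nk = dims
    return flat.reshape(nk, nj, ni, 3).transpose(2, 1, 0, 3).astype(float)


def write_deformable_reg(rec: DeformableRegRecord, path,
                         description: str = "regqa fixture",
                         uid_entropy: Optional[str] = None) -> Path:
    """Write a minimal Deformable Spatial Registration object.

    Displacements are stored as little-endian float32 (standard Vector
    Grid Data practice), so round-trips are lossless only at float32
    precision.
    """
    path = Path(path)
    ds = Dataset()
    ds.file_meta = _file_meta(DEFORMABLE_REG_SOP_CLASS, uid_entropy)
    ds.SOPClassUID = DEFORMABLE_REG_SOP_CLASS
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.Modality = "REG"
    ds.ContentDescription = description

    g = rec.dvf
    item = Dataset()
    grid = Dataset()
    with _quiet_ds():
        grid.ImagePositionPatient = [_fmt(v) for v in g.origin]
    grid.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    grid.GridDimensions = [int(n) for n in g.dims]
    grid.GridResolution = [float(v) for v in g.spacing]
    grid.VectorGridData = _flatten_dvf(g.displacements).tobytes()
    item.DeformableRegistrationGridSequence = [grid]
    if rec.pre_rigid is not None:
        item.PreDeformationMatrixRegistrationSequence = [_matrix_item(rec.pre_rigid)]
    if rec.post_rigid is not None:
        item.PostDeformationMatrixRegistrationSequence = [_matrix_item(rec.post_rigid)]
    ds.DeformableRegistrationSequence = [item]

    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*maximum length of 16.*")
        ds.save_as(path, enforce_file_format=True)
    return path


def read_deformable_reg(path) -> DeformableRegRecord:
    """Read a Deformable Spatial Registration object into a record.

    The declared grid dimensions must match the Vector Grid Data length
    (3 float32 per voxel) exactly; a truncated or padded stream raises.
    """
    path = Path(path)
    try:
        ds = pydicom.dcmread(path)
        seq = ds.DeformableRegistrationSequence
    except Exception as e:
        raise ParseError(f"not a readable deformable registration object: {e}") from None
    item = seq[0]
    grid = item.DeformableRegistrationGridSequence[0]
    dims = tuple(int(n) for n in grid.GridDimensions)
    spacing = np.array([float(v) for v in grid.GridResolution])
    origin = np.array([float(v) for v in grid.ImagePositionPatient])
    flat = np.frombuffer(grid.VectorGridData, dtype="<f4")
    expected = 3 * int(np.prod(dims))
    if flat.size != expected:
        raise GeometryError(
            f"vector grid data has {flat.size} values but dims {dims} require {expected}"
        )
    dvf = DVFGrid(origin, spacing, _unflatten_dvf(flat, dims))

    def _read_matrix(tag: str) -> Optional[HomogeneousTransform]:
        if tag not in item:
            return None
        mat = item[tag].value[0]
        return HomogeneousTransform.from_flat(
            [float(v) for v in mat.FrameOfReferenceTransformationMatrix]
        )

    return DeformableRegRecord(
        dvf,
        pre_rigid=_read_matrix("PreDeformationMatrixRegistrationSequence"),
        post_rigid=_read_matrix("PostDeformationMatrixRegistrationSequence"),
        provenance={"source": str(path)},
    )


# ---------------------------------------------------------------------------
# landmark lists

_SPLIT_RE = re.compile(r"[,;\s]+")


def read_landmarks(path, dialect: str, index_base: int = 0,
                   origin=None, spacing=None) -> LandmarkFile:
    """Read a 3-column delimited landmark list and convert to mm.

    ``dialect`` must be declared: ``"mm"`` for physical coordinates or
    ``"voxel_index"`` for grid indices, which are converted via
    ``origin + (index - index_base) * spacing`` and therefore require the
    grid geometry.  Comment lines (#) and a single leading header row of
    non-numeric column names are tolerated; any other non-numeric row
    raises with its line number.
    """
    if dialect not in ("mm", "voxel_index"):
        raise ValueError(f"dialect must be 'mm' or 'voxel_index', got {dialect!r}")
    if index_base not in (0, 1):
        raise ValueError(f"index_base must be 0 or 1, got {index_base!r}")
    if dialect == "voxel_index":
        if origin is None or spacing is None:
            raise GeometryError("voxel_index dialect requires origin and spacing")
        origin = np.asarray(origin, dtype=float).reshape(3)
        spacing = np.asarray(spacing, dtype=float).reshape(3)
        if np.any(spacing <= 0):
            raise GeometryError(f"spacing must be positive, got {spacing}")

    path = Path(path)
    pts = []
    header_allowed = True
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        s = line.strip()
        if not s or s.startswith("#"):
            continue
        tokens = [tok for tok in _SPLIT_RE.split(s) if tok]
        try:
            row = [float(tok) for tok in tokens]
        except ValueError:
            if header_allowed:
                header_allowed = False
                continue
            raise ParseError(f"{path.name}:{lineno}: non-numeric row {s!r}") from None
        header_allowed = False
        if len(row) != 3:
            raise ParseError(f"{path.name}:{lineno}: expected 3 columns, got {len(row)}")
        pts.append(row)
    if not pts:
        raise ParseError(f"{path.name}: no landmark rows found")
    pts = np.asarray(pts, dtype=float)
    if dialect == "voxel_index":
        pts = origin + (pts - index_base) * spacing
    if not np.all(np.isfinite(pts)):
        raise ParseError(f"{path.name}: non-finite landmark coordinates")
    return LandmarkFile(pts, dialect=dialect, index_base=index_base, source=str(path))


def write_landmarks(points, path, header: Optional[Sequence[str]] = ("x_mm", "y_mm", "z_mm")
                    ) -> Path:
    """Write landmarks as whitespace-delimited text (mm dialect)."""
    path = Path(path)
    pts = np.asarray(points, dtype=float).reshape(-1, 3)
    lines = []
    if header:
        lines.append("\t".join(header))
    lines += ["\t".join(repr(float(v)) for v in p) for p in pts]
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# masks (NRRD via SimpleITK)

def write_mask(mask: MaskVolume, path) -> Path:
    """Write a binary mask as an NRRD labelled volume with its geometry."""
    import SimpleITK as sitk

    path = Path(path)
    img = sitk.GetImageFromArray(mask.data.astype(np.uint8).transpose(2, 1, 0))
    img.SetOrigin(tuple(float(v) for v in mask.origin))
    img.SetSpacing(tuple(float(v) for v in mask.spacing))
    sitk.WriteImage(img, str(path))
    return path


def read_mask(path, name: str = "") -> MaskVolume:
    """Read a binary label volume (NRRD or any ITK-readable format).

    Non-identity direction matrices are rejected: this toolkit's geometry
    model is strictly axis-aligned LPS (point = origin + index * spacing).
    """
    import SimpleITK as sitk

    path = Path(path)
    try:
        img = sitk.ReadImage(str(path))
    except Exception as e:
        raise ParseError(f"cannot read mask {path.name}: {e}") from None
    if img.GetDimension() != 3:
        raise GeometryError(f"mask must be 3-D, got {img.GetDimension()}-D")
    direction = np.asarray(img.GetDirection()).reshape(3, 3)
    if not np.allclose(direction, np.eye(3), atol=1e-6):
        raise GeometryError(f"non-axis-aligned direction matrix unsupported: {direction}")
    arr = sitk.GetArrayFromImage(img)  # (z, y, x)
    return MaskVolume(
        origin=np.array(img.GetOrigin()),
        spacing=np.array(img.GetSpacing()),
        data=arr.transpose(2, 1, 0) != 0,
        name=name or path.stem,
    )
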