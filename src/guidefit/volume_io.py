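"""Reading and writing CT volumes and triangle meshes.

Supported formats: DICOM series (read-only), NRRD (read/write, via
SimpleITK), binary STL and ascii PLY (read/write, via trimesh).  Only
axis-aligned volumes are supported; oblique DICOM orientations are rejected
with a clear error rather than silently misinterpreted.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pydicom
import SimpleITK as sitk
import trimesh

from .core import GuidefitError, ParameterError, VoxelVolume

__all__ = [
    "read_dicom_series",
    "read_volume",
    "write_volume",
    "read_mesh",
    "write_mesh",
]

log = logging.getLogger(__name__)

_GAP_TOL = 0.01  # fractional tolerance on inter-slice spacing uniformity


def read_dicom_series(directory) -> VoxelVolume:
    """Load a single-series stack of axial CT slices as a volume.

    Slices are sorted by position along the slice normal; intensities are
    rescaled by slope/intercept; spacing comes from PixelSpacing plus the
    measured inter-slice distance; the origin is the position of the first
    (sorted) slice.
    """
    directory = Path(directory)
    files = sorted(p for p in directory.iterdir() if p.is_file())
    slices = []
    for p in files:
        try:
            ds = pydicom.dcmread(p)
        except Exception:
            continue
        if hasattr(ds, "PixelData"):
            slices.append(ds)
    if len(slices) < 2:
        raise GuidefitError(
            f"need at least 2 slices of one series in {directory}, found {len(slices)}"
        )
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in slices}
    if len(uids) != 1:
        raise GuidefitError(f"mixed series in {directory}: {sorted(map(str, uids))}")

    iop = np.asarray(slices[0].ImageOrientationPatient, dtype=float)
    row, col = iop[:3], iop[3:]
    if not (np.allclose(np.abs(row), [1, 0, 0], atol=1e-6) and np.allclose(np.abs(col), [0, 1, 0], atol=1e-6)):
        raise GuidefitError(
            f"oblique orientation not supported (ImageOrientationPatient={iop.tolist()}); "
            "only axis-aligned axial stacks are handled"
        )
    normal = np.cross(row, col)
    positions = np.array([np.asarray(ds.ImagePositionPatient, dtype=float) for ds in slices])
    along = positions @ normal
    order = np.argsort(along)
    slices = [slices[i] for i in order]
    positions = positions[order]
    along = along[order]

    gaps = np.diff(along)
    if np.any(gaps <= 0):
        raise GuidefitError("duplicate or non-monotonic slice positions in series")
    mean_gap = gaps.mean()
    if np.any(np.abs(gaps - mean_gap) > _GAP_TOL * mean_gap):
        worst = gaps[np.argmax(np.abs(gaps - mean_gap))]
        raise GuidefitError(
            f"non-uniform slice gap: found {worst:.6g} mm vs mean {mean_gap:.6g} mm "
            f"(tolerance {100 * _GAP_TOL:.0f}%)"
        )

    ps = [np.asarray(ds.PixelSpacing, dtype=float) for ds in slices]
    if not all(np.allclose(p, ps[0]) for p in ps):
        raise GuidefitError("in-plane pixel spacing differs between slices")
    dy, dx = ps[0]  # PixelSpacing is (row spacing, column spacing)

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = getattr(ds, "RescaleSlope", None)
        intercept = getattr(ds, "RescaleIntercept", None)
        if slope is None or intercept is None:
            warnings.warn(
                "missing RescaleSlope/RescaleIntercept; assuming slope 1, intercept 0",
                stacklevel=2,
            )
            slope, intercept = 1.0, 0.0
        planes.append(arr * float(slope) + float(intercept))
    # pixel_array is (rows, cols) = (y, x); volume layout is (x, y, z)
    data = np.stack(planes, axis=-1).transpose(1, 0, 2)
    spacing = np.array([dx, dy, float(mean_gap)])
    origin = positions[0]
    return VoxelVolume(data=data, spacing=spacing, origin=origin)


def _check_nrrd_header(path: Path) -> None:
    """Reject NRRD files without explicit spacing information."""
    with open(path, "rb") as fh:
        head = fh.read(4096).split(b"\n\n", 1)[0].decode("ascii", errors="replace")
    keys = {line.split(":", 1)[0].strip().lower() for line in head.splitlines() if ":" in line}
    if not ({"space directions", "spacings"} & keys):
        raise GuidefitError(f"{path}: NRRD header carries no spacing information")


def read_volume(path) -> VoxelVolume:
    """Read a scalar volume (NRRD); spacing and origin come from the header."""
    path = Path(path)
    if path.suffix.lower() not in {".nrrd", ".nhdr"}:
        raise GuidefitError(f"unknown volume format: {path.suffix!r} (expected .nrrd)")
    if not path.exists():
        raise GuidefitError(f"no such file: {path}")
    _check_nrrd_header(path)
    img = sitk.ReadImage(str(path))
    direction = np.asarray(img.GetDirection(), dtype=float).reshape(3, 3)
    if not np.allclose(np.abs(direction), np.eye(3), atol=1e-6):
        raise GuidefitError(f"{path}: oblique volume orientations are not supported")
    # SimpleITK arrays are (z, y, x); package layout is (x, y, z)
    data = sitk.GetArrayFromImage(img).transpose(2, 1, 0)
    # fold any axis flips in the direction matrix into the data/origin
    signs = np.sign(np.diag(direction))
    origin = np.asarray(img.GetOrigin(), dtype=float)
    spacing = np.asarray(img.GetSpacing(), dtype=float)
    for ax in range(3):
        if signs[ax] < 0:
            data = np.flip(data, axis=ax)
            origin[ax] = origin[ax] - spacing[ax] * (data.shape[ax] - 1)
    return VoxelVolume(data=np.ascontiguousarray(data), spacing=spacing, origin=origin)


def write_volume(volume: VoxelVolume, path) -> None:
    """Write a volume as NRRD; round-trips data, spacing and origin exactly."""
    path = Path(path)
    if path.suffix.lower() != ".nrrd":
        raise GuidefitError(f"unknown volume format: {path.suffix!r} (expected .nrrd)")
    img = sitk.GetImageFromArray(np.ascontiguousarray(volume.data.transpose(2, 1, 0)))
    img.SetSpacing(tuple(float(s) for s in volume.spacing))
    img.SetOrigin(tuple(float(o) for o in volume.origin))
    sitk.WriteImage(img, str(path))


_MERGE_TOL = 1e-6  # mm; STL stores duplicated vertices per facet


def read_mesh(path) -> trimesh.Trimesh:
    """Load an STL/PLY mesh, merging duplicate vertices and cleaning faces.

    Degenerate (repeated-index or zero-area) and exactly duplicated faces are
    dropped; the number of dropped faces is logged and recorded in
    ``mesh.metadata["cleaned_face_count"]``.
    """
    path = Path(path)
    if not path.exists():
        raise GuidefitError(f"no such file: {path}")
    ext = path.suffix.lower().lstrip(".")
    if ext not in {"stl", "ply"}:
        raise GuidefitError(f"unknown mesh format: {path.suffix!r} (expected .stl or .ply)")
    try:
        mesh = trimesh.load(str(path), file_type=ext, process=False)
    except Exception as exc:  # unreadable / empty
        raise GuidefitError(f"could not read mesh {path}: {exc}") from exc
    if not isinstance(mesh, trimesh.Trimesh) or len(mesh.vertices) == 0 or len(mesh.faces) == 0:
        raise GuidefitError(f"{path} contains no triangle geometry")
    verts = mesh.vertices.view(np.ndarray).astype(float)
    faces = mesh.faces.view(np.ndarray).astype(np.int64)
    # merge vertices within tolerance (STL duplicates per facet)
    key = np.round(verts / _MERGE_TOL).astype(np.int64)
    _, first, inverse = np.unique(key, axis=0, return_index=True, return_inverse=True)
    verts = verts[first]
    faces = inverse[faces]
    n0 = len(faces)
    # drop faces with repeated vertices
    ok = (faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2]) & (faces[:, 0] != faces[:, 2])
    faces = faces[ok]
    # drop exact duplicates (same vertex triple regardless of winding)
    _, keep = np.unique(np.sort(faces, axis=1), axis=0, return_index=True)
    faces = faces[np.sort(keep)]
    # drop zero-area faces
    tri = verts[faces]
    areas = 0.5 * np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]), axis=1)
    faces = faces[areas > 1e-14]
    cleaned = n0 - len(faces)
    if len(faces) == 0:
        raise GuidefitError(f"{path}: no valid faces after cleaning")
    out = trimesh.Trimesh(vertices=verts, faces=faces, process=False)
    out.metadata["cleaned_face_count"] = int(cleaned)
    if cleaned:
        log.info("cleaned %d degenerate/duplicate faces from %s", cleaned, path)
    if not out.is_winding_consistent:
        log.warning("%s: inconsistent winding; signed distances may be unreliable", path)
        out.metadata["winding_consistent"] = False
    return out


def write_mesh(mesh: trimesh.Trimesh, path) -> None:
    """Write a mesh as binary STL or ascii PLY, chosen by extension."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext == ".stl":
        data = mesh.export(file_type="stl")  # binary
        path.write_bytes(data)
    elif ext == ".ply":
        data = mesh.export(file_type="ply", encoding="ascii")
        if isinstance(data, str):
            data = data.encode("ascii")
        path.write_bytes(data)
    else:
        raise GuidefitError(f"unknown mesh format: {path.suffix!r} (expected .stl or .ply)")
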