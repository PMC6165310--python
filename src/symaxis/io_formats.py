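"""Point-cloud containers and file I/O (PLY, PCD, XYZ) plus result records.

No geometry lives here: readers never reorder, deduplicate or rescale points
beyond the explicit ``scale`` factor, and writers emit files the readers can
round-trip.

Coordinates are centimetres throughout the package.  Files recorded in other
units are converted on read with ``scale`` (e.g. ``scale=100`` for
metre-valued exports).  The camera viewpoint defaults to the origin and +z
points into the scene.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .exceptions import CloudIOError, CloudParseError, EmptyCloudError, ParameterError

__all__ = [
    "PointCloud",
    "read_cloud",
    "write_cloud",
    "write_result",
    "read_result",
]

_ORIGIN = (0.0, 0.0, 0.0)


@dataclass
class PointCloud:
    """A single-object point cloud in the camera frame.

    Parameters
    ----------
    points:
        ``(n, 3)`` float array of positions in cm.  Must be nonempty and
        finite.
    normals:
        Optional ``(n, 3)`` array of unit surface normals, one per point and
        in the same order.
    viewpoint:
        Camera position ``pv`` in the same frame; defaults to the origin.
    """

    points: np.ndarray
    normals: Optional[np.ndarray] = None
    viewpoint: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.points = np.ascontiguousarray(self.points, dtype=np.float64)
        if self.points.ndim != 2 or self.points.shape[1] != 3:
            raise ParameterError(
                f"points must be an (n, 3) array, got shape {self.points.shape}"
            )
        if len(self.points) == 0:
            raise EmptyCloudError("point cloud is empty")
        if not np.all(np.isfinite(self.points)):
            raise ParameterError("points contain non-finite coordinates")
        self.viewpoint = np.asarray(self.viewpoint, dtype=np.float64).reshape(3)
        if self.normals is not None:
            self.normals = np.ascontiguousarray(self.normals, dtype=np.float64)
            if self.normals.shape != self.points.shape:
                raise ParameterError(
                    "normals must match points: "
                    f"{self.normals.shape} vs {self.points.shape}"
                )
            norms = np.linalg.norm(self.normals, axis=1)
            if not np.allclose(norms, 1.0, atol=1e-6):
                raise ParameterError("normals must be unit vectors (|n| = 1 ± 1e-6)")

    def __len__(self) -> int:
        return len(self.points)

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def without_normals(self) -> "PointCloud":
        return replace(self, normals=None)

    def select(self, mask_or_indices) -> "PointCloud":
        """Subset preserving order; normals follow points."""
        pts = self.points[mask_or_indices]
        nrm = None if self.normals is None else self.normals[mask_or_indices]
        return PointCloud(pts, nrm, self.viewpoint.copy())


# ---------------------------------------------------------------------------
# readers


def _finish(points: np.ndarray, normals, scale: float, viewpoint) -> PointCloud:
    points = np.asarray(points, dtype=np.float64) * float(scale)
    if normals is not None:
        normals = np.asarray(normals, dtype=np.float64)
        norms = np.linalg.norm(normals, axis=1, keepdims=True)
        if np.any(norms == 0):
            raise CloudParseError("file carries a zero-length normal vector")
        normals = normals / norms
    return PointCloud(points, normals, np.asarray(viewpoint, dtype=np.float64))


def _read_ply(path: Path, scale: float, viewpoint) -> PointCloud:
    # trimesh handles both ascii and binary-little-endian PLY; raw vertex
    # properties (nx/ny/nz) are only preserved in its _ply_raw metadata.
    import trimesh

    try:
        obj = trimesh.load(str(path), process=False)
    except Exception as exc:  # noqa: BLE001 - re-raise as package error
        raise CloudParseError(f"could not parse PLY file {path}: {exc}") from exc
    raw = getattr(obj, "metadata", {}).get("_ply_raw", {}).get("vertex", {})
    data = raw.get("data", {})
    if isinstance(data, np.ndarray):  # structured array for binary files
        data = {name: data[name] for name in data.dtype.names}
    try:
        points = np.column_stack([data["x"], data["y"], data["z"]])
    except KeyError as exc:
        raise CloudParseError(f"PLY file {path} lacks x/y/z vertex properties") from exc
    if len(points) == 0:
        raise EmptyCloudError(f"PLY file {path} declares zero vertices")
    normals = None
    if all(k in data for k in ("nx", "ny", "nz")):
        normals = np.column_stack([data["nx"], data["ny"], data["nz"]])
    return _finish(points, normals, scale, viewpoint)


def _read_xyz(path: Path, scale: float, viewpoint) -> PointCloud:
    import warnings

    try:
        with warnings.catch_warnings():
            # empty files raise EmptyCloudError below; no need for the
            # loadtxt UserWarning on top
            warnings.simplefilter("ignore", UserWarning)
            arr = np.loadtxt(str(path), dtype=np.float64, ndmin=2)
    except ValueError as exc:
        raise CloudParseError(f"malformed XYZ record in {path}: {exc}") from exc
    if arr.size == 0:
        raise EmptyCloudError(f"XYZ file {path} contains no points")
    if arr.shape[1] == 3:
        return _finish(arr, None, scale, viewpoint)
    if arr.shape[1] >= 6:
        return _finish(arr[:, :3], arr[:, 3:6], scale, viewpoint)
    raise CloudParseError(
        f"XYZ file {path} has {arr.shape[1]} columns; expected 3 (xyz) or 6 (+normals)"
    )


_PCD_NORMAL_FIELDS = (("nx", "ny", "nz"), ("normal_x", "normal_y", "normal_z"))


def _read_pcd(path: Path, scale: float, viewpoint) -> PointCloud:
    """Minimal ASCII PCD reader (header + whitespace rows)."""
    fields: list[str] = []
    rows: list[list[float]] = []
    in_header = True
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if in_header:
                key, *vals = line.split()
                key = key.upper()
                if key == "FIELDS":
                    fields = [v.lower() for v in vals]
                elif key == "DATA":
                    if vals and vals[0].lower() != "ascii":
                        raise CloudParseError(
                            f"{path}: only DATA ascii PCD files are supported, "
                            f"got {vals[0]!r}"
                        )
                    in_header = False
                continue
            try:
                rows.append([float(v) for v in line.split()])
            except ValueError as exc:
                raise CloudParseError(f"{path}: malformed PCD row at line {lineno}") from exc
    if in_header:
        raise CloudParseError(f"{path}: no DATA section found in PCD header")
    if not rows:
        raise EmptyCloudError(f"PCD file {path} contains no points")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise CloudParseError(f"{path}: ragged PCD rows")
    arr = np.asarray(rows, dtype=np.float64)
    try:
        cols = {f: arr[:, i] for i, f in enumerate(fields)}
        points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    except (KeyError, IndexError) as exc:
        raise CloudParseError(f"{path}: PCD FIELDS lack x/y/z") from exc
    normals = None
    for trio in _PCD_NORMAL_FIELDS:
        if all(f in cols for f in trio):
            normals = np.column_stack([cols[f] for f in trio])
            break
    return _finish(points, normals, scale, viewpoint)


_READERS = {"ply": _read_ply, "pcd": _read_pcd, "xyz": _read_xyz}


def read_cloud(
    path,
    format: str = "auto",
    scale: float = 1.0,
    viewpoint: Sequence[float] = _ORIGIN,
) -> PointCloud:
    """Read a point cloud from ``path``.

    ``format`` is one of ``ply``, ``pcd``, ``xyz`` or ``auto`` (detect from
    the extension; unknown extensions fall back to whitespace XYZ).  ``scale``
    multiplies all coordinates on read, converting the file's unit to cm.
    Point order is preserved exactly; normals are loaded when the file carries
    them and are re-normalised to unit length.
    """
    path = Path(path)
    if not path.is_file():
        raise CloudIOError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        ext = path.suffix.lower().lstrip(".")
        fmt = ext if ext in _READERS else "xyz"
    if fmt not in _READERS:
        raise ParameterError(f"unknown cloud format {format!r}; use ply, pcd, xyz or auto")
    return _READERS[fmt](path, scale, viewpoint)


# ---------------------------------------------------------------------------
# writers


def _write_ply(cloud: PointCloud, path: Path) -> None:
    n = len(cloud)
    props = ["x", "y", "z"] + (["nx", "ny", "nz"] if cloud.has_normals else [])
    header = ["ply", "format ascii 1.0", f"element vertex {n}"]
    header += [f"property float {p}" for p in props]
    header.append("end_header")
    body = (
        cloud.points
        if not cloud.has_normals
        else np.hstack([cloud.points, cloud.normals])
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, body, fmt="%.9g")


def _write_xyz(cloud: PointCloud, path: Path) -> None:
    body = (
        cloud.points
        if not cloud.has_normals
        else np.hstack([cloud.points, cloud.normals])
    )
    np.savetxt(str(path), body, fmt="%.9g")


def write_cloud(cloud: PointCloud, path, format: str = "auto") -> None:
    """Write ``cloud`` as ASCII PLY or XYZ text; round-trips through
    :func:`read_cloud` to 1e-6."""
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "ply" if path.suffix.lower() == ".ply" else "xyz"
    if fmt not in ("ply", "xyz"):
        raise ParameterError(f"unsupported write format {format!r}; use ply or xyz")
    try:
        (_write_ply if fmt == "ply" else _write_xyz)(cloud, path)
    except OSError as exc:
        raise CloudIOError(f"cannot write {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# result records


def write_result(result, path, include_plane_scores: bool = True) -> None:
    """Serialize a :class:`~symaxis.symmetry.SymmetryResult` as JSON."""
    rec = result.to_dict(include_plane_scores=include_plane_scores)
    try:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(rec, fh, indent=2)
            fh.write("\n")
    except OSError as exc:
        raise CloudIOError(f"cannot write {path}: {exc}") from exc


def read_result(path) -> dict:
    """Parse a result record written by :func:`write_result`."""
    try:
        with open(path, "r", encoding="utf-8") as fh:
            rec = json.load(fh)
    except OSError as exc:
        raise CloudIOError(f"cannot read {path}: {exc}") from exc
    except json.JSONDecodeError as exc:
        raise CloudParseError(f"malformed result record {path}: {exc}") from exc
    for key in ("centroid", "plane_normal", "score", "axis"):
        if key not in rec:
            raise CloudParseError(f"result record {path} lacks field {key!r}")
    return rec
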