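"""Point-cloud and result-table I/O.

The universal in-memory container is :class:`PointCloud`: an ``(n, 3)``
float64 array of x, y, z coordinates in meters plus a ``source_id`` label.
Clouds are expected to be height-normalized (z = height above ground) with
ground returns already removed; a warning is emitted when ``min z < -0.5 m``
suggests otherwise.

Supported on-disk formats: plain-text XYZ (whitespace- or comma-separated,
first three numeric columns are x, y, z, extra columns ignored, optional
header) and LAS/LAZ through :mod:`laspy` when it is installed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyCloudError, InputError

__all__ = [
    "PointCloud",
    "BoundingBox",
    "IndexRecord",
    "INDEX_RECORD_COLUMNS",
    "read_point_cloud",
    "write_point_cloud",
    "crop_to_plot",
    "bounding_box",
    "as_points",
    "write_index_records",
    "read_index_records",
]

#: Fixed column order of the per-plot results CSV.
INDEX_RECORD_COLUMNS = [
    "source_id",
    "n_points",
    "db",
    "ce",
    "ce_xy",
    "ce_xz",
    "ce_yz",
    "sdb_detected",
    "final_voxel_size",
    "t_db",
    "t_ce",
]


@dataclass(frozen=True)
class PointCloud:
    """An ordered collection of 3D points in meters.

    Parameters
    ----------
    points : ndarray of shape (n, 3)
        Finite x, y, z coordinates; at least one point.
    source_id : str
        Plot or file identifier carried through the pipeline.
    """

    points: np.ndarray
    source_id: str = ""

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=np.float64)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise InputError(
                f"point array must have shape (n, 3), got {pts.shape}"
            )
        if pts.shape[0] == 0:
            raise EmptyCloudError(
                f"point cloud {self.source_id!r} contains no points"
            )
        if not np.isfinite(pts).all():
            raise InputError(
                f"point cloud {self.source_id!r} contains non-finite coordinates"
            )
        object.__setattr__(self, "points", pts)
        if pts[:, 2].min() < -0.5:
            warnings.warn(
                f"cloud {self.source_id!r}: min z = {pts[:, 2].min():.2f} m < -0.5 m; "
                "input may not be height-normalized with ground removed",
                stacklevel=2,
            )

    def __len__(self) -> int:
        return self.points.shape[0]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned bounding box of a cloud, meters."""

    min_corner: np.ndarray
    max_corner: np.ndarray

    @property
    def extents(self) -> np.ndarray:
        return self.max_corner - self.min_corner


@dataclass
class IndexRecord:
    """Per-plot output row: both indices, SDB outcome and timings."""

    source_id: str
    n_points: int
    db: float
    ce: float
    ce_xy: float
    ce_xz: float
    ce_yz: float
    sdb_detected: bool
    final_voxel_size: float | None = None
    t_db: float = float("nan")
    t_ce: float = float("nan")

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in INDEX_RECORD_COLUMNS}
        if d["final_voxel_size"] is None:
            d["final_voxel_size"] = float("nan")
        return d


def as_points(cloud) -> np.ndarray:
    """Coerce a PointCloud or array-like into an (n, 3) float64 array."""
    if isinstance(cloud, PointCloud):
        return cloud.points
    pts = np.asarray(cloud, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[1] != 3:
        raise InputError(f"expected an (n, 3) point array, got shape {pts.shape}")
    if pts.shape[0] == 0:
        raise EmptyCloudError("empty point array")
    if not np.isfinite(pts).all():
        raise InputError("point array contains non-finite coordinates")
    return pts


def _read_xyz(path: Path) -> np.ndarray:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.replace(",", " ").split()
            if len(parts) < 3:
                continue
            try:
                rows.append([float(parts[0]), float(parts[1]), float(parts[2])])
            except ValueError:
                if lineno == 1:
                    continue  # header line
                raise InputError(
                    f"{path}: line {lineno} is not numeric: {line.strip()!r}"
                )
    return np.asarray(rows, dtype=np.float64).reshape(-1, 3)


def _read_las(path: Path) -> np.ndarray:
    try:
        import laspy
    except ImportError as exc:  # pragma: no cover - laspy optional
        raise InputError(
            f"{path}: reading LAS/LAZ requires the optional 'laspy' dependency "
            "(pip install canopy-complexity[las])"
        ) from exc
    with laspy.open(path) as reader:
        las = reader.read()
    return np.column_stack([las.x, las.y, las.z]).astype(np.float64)


def read_point_cloud(path, format: str = "auto") -> PointCloud:
    """Read a point cloud from LAS/LAZ or plain-text XYZ.

    Parameters
    ----------
    path : path-like
    format : {"auto", "las", "laz", "xyz"}
        ``auto`` dispatches on the file suffix (``.las``/``.laz`` vs text).

    Returns
    -------
    PointCloud
        All points, order preserved from the file, coordinates in meters.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    fmt = format.lower()
    if fmt == "auto":
        fmt = "las" if path.suffix.lower() in (".las", ".laz") else "xyz"
    if fmt in ("las", "laz"):
        pts = _read_las(path)
    elif fmt == "xyz":
        pts = _read_xyz(path)
    else:
        raise InputError(f"unknown point-cloud format: {format!r}")
    if pts.shape[0] == 0:
        raise EmptyCloudError(f"{path}: no points parsed")
    return PointCloud(pts, source_id=path.stem)


def write_point_cloud(cloud, path, format: str = "auto") -> None:
    """Write a cloud as XYZ text or LAS/LAZ (laspy required for the latter).

    LAS files use a coordinate scale of 0.001 m, so a round-trip preserves
    coordinates to 1e-3 m; the XYZ text path round-trips at full float
    precision (17 significant digits).
    """
    pts = as_points(cloud)
    path = Path(path)
    fmt = format.lower()
    if fmt == "auto":
        fmt = "las" if path.suffix.lower() in (".las", ".laz") else "xyz"
    if fmt in ("las", "laz"):
        try:
            import laspy
        except ImportError as exc:  # pragma: no cover - laspy optional
            raise InputError(
                "writing LAS/LAZ requires the optional 'laspy' dependency"
            ) from exc
        header = laspy.LasHeader(point_format=0, version="1.2")
        header.scales = np.array([0.001, 0.001, 0.001])
        header.offsets = pts.min(axis=0)
        las = laspy.LasData(header)
        las.x, las.y, las.z = pts[:, 0], pts[:, 1], pts[:, 2]
        las.write(path)
    elif fmt == "xyz":
        np.savetxt(path, pts, fmt="%.17g")
    else:
        raise InputError(f"unknown point-cloud format: {format!r}")


def crop_to_plot(cloud: PointCloud, center_xy: Sequence[float], side: float) -> PointCloud:
    """Crop to a vertical square column around ``center_xy``.

    Keeps exactly the points with ``|x - cx| <= side/2`` and
    ``|y - cy| <= side/2`` (closed intervals, all z retained).
    """
    if side <= 0:
        raise InputError(f"side must be positive, got {side}")
    pts = as_points(cloud)
    cx, cy = float(center_xy[0]), float(center_xy[1])
    half = side / 2.0
    mask = (np.abs(pts[:, 0] - cx) <= half) & (np.abs(pts[:, 1] - cy) <= half)
    if not mask.any():
        raise EmptyCloudError(
            f"no points within the {side} m window centered at ({cx}, {cy})"
        )
    source = cloud.source_id if isinstance(cloud, PointCloud) else ""
    return PointCloud(pts[mask], source_id=source)


def bounding_box(cloud) -> BoundingBox:
    """Componentwise min/max corners of a non-empty cloud."""
    pts = as_points(cloud)
    return BoundingBox(pts.min(axis=0), pts.max(axis=0))


def write_index_records(records: Iterable[IndexRecord], path) -> pd.DataFrame:
    """Write per-plot records as CSV with the fixed column header."""
    df = pd.DataFrame([r.as_dict() for r in records], columns=INDEX_RECORD_COLUMNS)
    df.to_csv(path, index=False)
    return df


def read_index_records(path) -> pd.DataFrame:
    """Read a per-plot results CSV, validating the fixed header."""
    df = pd.read_csv(path)
    missing = [c for c in INDEX_RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"{path}: missing result columns {missing}")
    return df
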