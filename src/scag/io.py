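"""Point-cloud and result-table input/output, plus statistical outlier removal.

Conventions
-----------
* A :class:`PointCloud` stores one plant: an (n, 3) float array with the z
  axis vertical and the plant base at minimal z.  Readers never reorient.
* Every cloud declares its length unit (``mm`` | ``cm`` | ``m``); all
  algorithm parameters are interpreted in that unit.
* Supported formats: PLY (ASCII and binary little-endian ``vertex`` elements
  with x/y/z; other properties ignored) and delimited text (``.xyz``,
  ``.txt``, ``.csv``) with whitespace or comma separators; columns beyond
  x, y, z are ignored.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

UNITS = ("mm", "cm", "m")
#: factors to centimetres, the unit the CLI states its defaults in
UNIT_TO_CM = {"mm": 0.1, "cm": 1.0, "m": 100.0}

ANGLE_CSV_HEADER = [
    "plant_id",
    "node_x", "node_y", "node_z",
    "branch1_x", "branch1_y", "branch1_z",
    "branch2_x", "branch2_y", "branch2_z",
    "angle_deg",
]


class PointCloudError(ValueError):
    """Malformed or empty point-cloud input."""


@dataclass(frozen=True)
class PointCloud:
    """A single-plant 3D point cloud with a declared length unit."""

    points: np.ndarray
    plant_id: str = "plant"
    unit: str = "cm"

    def __post_init__(self):
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise PointCloudError("points must be an (n, 3) array")
        if len(pts) == 0:
            raise PointCloudError("empty point cloud")
        if not np.all(np.isfinite(pts)):
            raise PointCloudError("non-finite coordinates in point cloud")
        if self.unit not in UNITS:
            raise PointCloudError(f"unit must be one of {UNITS}, got {self.unit!r}")
        object.__setattr__(self, "points", pts)

    def __len__(self) -> int:
        return len(self.points)

    @property
    def z(self) -> np.ndarray:
        return self.points[:, 2]

    @property
    def z_extent(self) -> float:
        return float(self.z.max() - self.z.min())

    def with_points(self, pts: np.ndarray) -> "PointCloud":
        return replace(self, points=pts)

    def to_unit(self, unit: str) -> "PointCloud":
        if unit not in UNITS:
            raise PointCloudError(f"unknown unit {unit!r}")
        factor = UNIT_TO_CM[self.unit] / UNIT_TO_CM[unit]
        return PointCloud(self.points * factor, self.plant_id, unit)


@dataclass(frozen=True)
class AngleRecord:
    """One detected branch: node point, two branch points, and the angle."""

    node_point: np.ndarray
    branch_point_1: np.ndarray
    branch_point_2: np.ndarray
    angle_deg: float
    plant_id: str = "plant"
    degraded: bool = False

    def __post_init__(self):
        for name in ("node_point", "branch_point_1", "branch_point_2"):
            v = np.asarray(getattr(self, name), dtype=float).reshape(3)
            object.__setattr__(self, name, v)

    @property
    def vec_a(self) -> np.ndarray:
        return self.branch_point_1 - self.node_point

    @property
    def vec_b(self) -> np.ndarray:
        return self.branch_point_2 - self.node_point


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_TEXT_EXT = {".xyz", ".txt", ".csv"}


def read_cloud(path: str | os.PathLike, unit: str = "cm", plant_id: str | None = None) -> PointCloud:
    """Read a point cloud from PLY or delimited text.

    Parameters
    ----------
    path : file path ending in ``.ply``, ``.xyz``, ``.txt`` or ``.csv``
    unit : declared length unit of the coordinates
    plant_id : defaults to the file stem
    """
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if plant_id is None:
        plant_id = os.path.splitext(os.path.basename(path))[0]
    if ext == ".ply":
        pts = _read_ply(path)
    elif ext in _TEXT_EXT:
        pts = _read_text(path)
    else:
        raise PointCloudError(f"unsupported extension {ext!r}")
    return PointCloud(pts, plant_id=plant_id, unit=unit)


def _read_ply(path: str) -> np.ndarray:
    import trimesh

    try:
        obj = trimesh.load(path, process=False)
    except Exception as exc:  # pragma: no cover - delegated parser detail
        raise PointCloudError(f"unreadable PLY file {path}: {exc}") from exc
    verts = np.asarray(obj.vertices, dtype=float)
    if verts.size == 0:
        raise PointCloudError(f"no vertices in {path}")
    return verts


def _read_text(path: str) -> np.ndarray:
    rows = []
    with open(path, "r") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.replace(",", " ").split()
            vals = []
            for p in parts:
                try:
                    vals.append(float(p))
                except ValueError:
                    break
            if len(vals) == 0 and ln == 1:
                continue  # tolerate a single header line
            if len(vals) < 3:
                raise PointCloudError(f"{path}:{ln}: fewer than 3 numeric columns")
            rows.append(vals[:3])
    if not rows:
        raise PointCloudError(f"no points in {path}")
    return np.asarray(rows, dtype=float)


def write_cloud(cloud: PointCloud, path: str | os.PathLike) -> None:
    """Write a cloud as ASCII PLY (double precision) or delimited text."""
    path = os.fspath(path)
    ext = os.path.splitext(path)[1].lower()
    if ext == ".ply":
        _write_ply_ascii(cloud.points, path)
    elif ext in _TEXT_EXT:
        delim = "," if ext == ".csv" else " "
        np.savetxt(path, cloud.points, fmt="%.9f", delimiter=delim)
    else:
        raise PointCloudError(f"unsupported extension {ext!r}")


def _write_ply_ascii(points: np.ndarray, path: str) -> None:
    # double-typed ASCII PLY so round-trips preserve coordinates to < 1e-6
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        fh.write(f"element vertex {len(points)}\n")
        fh.write("property double x\nproperty double y\nproperty double z\n")
        fh.write("end_header\n")
        for x, y, z in points:
            fh.write(f"{x:.9f} {y:.9f} {z:.9f}\n")


def write_angles(records: Sequence[AngleRecord], path: str | os.PathLike) -> None:
    """Write detected branches as CSV, one row per branch, fixed header."""
    with open(os.fspath(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(ANGLE_CSV_HEADER)
        for r in records:
            w.writerow(
                [r.plant_id]
                + [f"{v:.9f}" for v in r.node_point]
                + [f"{v:.9f}" for v in r.branch_point_1]
                + [f"{v:.9f}" for v in r.branch_point_2]
                + [f"{r.angle_deg:.9f}"]
            )


def read_angles(path: str | os.PathLike) -> list[AngleRecord]:
    """Read back an angle CSV produced by :func:`write_angles`."""
    out: list[AngleRecord] = []
    with open(os.fspath(path), "r", newline="") as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            out.append(
                AngleRecord(
                    node_point=[float(row[k]) for k in ("node_x", "node_y", "node_z")],
                    branch_point_1=[float(row[k]) for k in ("branch1_x", "branch1_y", "branch1_z")],
                    branch_point_2=[float(row[k]) for k in ("branch2_x", "branch2_y", "branch2_z")],
                    angle_deg=float(row["angle_deg"]),
                    plant_id=row["plant_id"],
                )
            )
    return out


# ---------------------------------------------------------------------------
# denoising
# ---------------------------------------------------------------------------

def denoise_sor(cloud: PointCloud, k: int = 16, std_mult: float = 1.0) -> PointCloud:
    """Statistical outlier removal.

    For every point the mean distance to its ``k`` nearest neighbours is
    computed; points whose statistic exceeds ``mean + std_mult * std`` of the
    global distribution are discarded.  Defaults follow common practice in
    point-cloud toolkits (k=16, one standard deviation).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if std_mult <= 0:
        raise ValueError("std_mult must be positive")
    n = len(cloud)
    if n <= k:
        raise ValueError(f"denoise_sor needs more than k={k} points, got {n}")
    tree = cKDTree(cloud.points)
    dists, _ = tree.query(cloud.points, k=k + 1)  # first neighbour is the point itself
    mean_knn = dists[:, 1:].mean(axis=1)
    thresh = mean_knn.mean() + std_mult * mean_knn.std()
    keep = mean_knn <= thresh
    return cloud.with_points(cloud.points[keep])
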