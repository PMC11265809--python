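"""Ground-truthed synthetic plant clouds.

The generator emulates a defoliated soybean-like plant as scanned by a
terrestrial laser scanner at ~2 mm resolution: a roughly vertical main stem
with mild lateral drift, straight branches attached at known heights and
known 3D angles, points sampled on the cylinder surfaces of stem and
branches, with optional Gaussian jitter, per-branch dropout and sparse
uniform outliers.  Every cloud carries a sidecar truth object (node points
and angles) so detection and angle accuracy can be scored without any
external dataset.

The branch angle stored as truth is the angle between the branch direction
and the local upward stem direction at the attachment point — the same
quantity the detector reports from its two branch-point vectors.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .geometry import angle_between_deg
from .io import PointCloud

__all__ = [
    "Branch", "GroundTruthSkeleton", "SamplingSpec", "SkeletonSpecError",
    "make_skeleton", "make_y_skeleton", "sample_cloud", "make_fixture_suite",
    "write_truth", "read_truth", "GROUP_SPECS",
]


class SkeletonSpecError(ValueError):
    """Infeasible skeleton specification (e.g. too many branches)."""


@dataclass(frozen=True)
class Branch:
    attach_point: np.ndarray      # true node, on the stem polyline
    direction: np.ndarray         # unit vector up the branch
    length: float
    radius: float
    stem_direction: np.ndarray    # unit local stem direction at the attachment

    def __post_init__(self):
        for name in ("attach_point", "direction", "stem_direction"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))


@dataclass(frozen=True)
class GroundTruthSkeleton:
    """Parametric stem/branch geometry with true node points and angles."""

    stem_polyline: np.ndarray     # (m, 3) ordered base -> top
    stem_radius: float
    branches: tuple
    true_angles: tuple            # degrees, one per branch
    unit: str = "cm"
    plant_id: str = "synthetic"

    @property
    def node_points(self) -> np.ndarray:
        if not self.branches:
            return np.empty((0, 3))
        return np.array([b.attach_point for b in self.branches])

    @property
    def height(self) -> float:
        z = self.stem_polyline[:, 2]
        return float(z.max() - z.min())


@dataclass(frozen=True)
class SamplingSpec:
    """Surface-sampling conditions; spacing defaults to the 2 mm scan grid."""

    spacing: float = 0.2          # cm
    jitter_sd: float = 0.0
    dropout: float = 0.0          # fraction of branch points removed
    n_outliers: int = 0
    seed: int = 0

    def __post_init__(self):
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")


# ---------------------------------------------------------------------------
# skeleton construction
# ---------------------------------------------------------------------------

def _stem_curve(height: float, amplitude: float, phases: np.ndarray):
    """Closed-form stem centreline x(z), y(z) and its unit tangent."""
    w = 2.0 * math.pi / height

    def point(z):
        return np.array([
            amplitude * math.sin(w * z + phases[0]),
            amplitude * math.sin(w * z + phases[1]),
            z,
        ])

    def tangent(z):
        t = np.array([
            amplitude * w * math.cos(w * z + phases[0]),
            amplitude * w * math.cos(w * z + phases[1]),
            1.0,
        ])
        return t / np.linalg.norm(t)

    return point, tangent


def make_skeleton(
    n_branches: int,
    angle_range: tuple[float, float] = (20.0, 50.0),
    height: float = 60.0,
    seed: int = 0,
    stem_radius: float = 0.25,
    branch_radius: float = 0.2,
    branch_length_range: tuple[float, float] = (8.0, 15.0),
    min_gap: float = 3.0,
    drift_amplitude: float = 0.5,
    unit: str = "cm",
    plant_id: str = "synthetic",
) -> GroundTruthSkeleton:
    """Random soybean-scale skeleton, fully determined by ``seed``.

    Branch attachment heights are kept at least ``min_gap`` apart inside the
    middle portion of the stem; azimuths are uniform on the circle and
    branch angles uniform in ``angle_range`` (degrees from the local upward
    stem direction).
    """
    lo, hi = angle_range
    if n_branches < 0:
        raise SkeletonSpecError("n_branches must be >= 0")
    if not (0.0 < lo <= hi < 180.0):
        raise SkeletonSpecError("angle range must satisfy 0 < lo <= hi < 180")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0.0, 2.0 * math.pi, size=2)
    point, tangent = _stem_curve(height, drift_amplitude, phases)

    z_lo, z_hi = 0.2 * height, 0.8 * height
    span = z_hi - z_lo
    slack = span - (n_branches - 1) * min_gap if n_branches > 1 else span
    if n_branches > 0 and slack < 0:
        raise SkeletonSpecError(
            f"{n_branches} branches need {(n_branches - 1) * min_gap:.1f} of stem, "
            f"only {span:.1f} available"
        )
    if n_branches > 0:
        u = np.sort(rng.uniform(0.0, 1.0, size=n_branches))
        attach_z = z_lo + u * slack + np.arange(n_branches) * min_gap
    else:
        attach_z = np.empty(0)

    branches = []
    angles = []
    for z in attach_z:
        theta = math.radians(rng.uniform(lo, hi))
        phi = rng.uniform(0.0, 2.0 * math.pi)
        u_stem = tangent(z)
        e = np.array([math.cos(phi), math.sin(phi), 0.0])
        w = e - np.dot(e, u_stem) * u_stem
        nw = np.linalg.norm(w)
        if nw < 1e-12:  # azimuth parallel to a tilted stem; nudge
            e = np.array([math.sin(phi), math.cos(phi), 0.0])
            w = e - np.dot(e, u_stem) * u_stem
            nw = np.linalg.norm(w)
        w /= nw
        direction = math.cos(theta) * u_stem + math.sin(theta) * w
        length = rng.uniform(*branch_length_range)
        branches.append(
            Branch(point(z), direction, float(length), branch_radius, u_stem)
        )
        angles.append(angle_between_deg(direction, u_stem))

    z_grid = np.linspace(0.0, height, max(2, int(height / 0.5) + 1))
    polyline = np.array([point(z) for z in z_grid])
    return GroundTruthSkeleton(
        stem_polyline=polyline,
        stem_radius=stem_radius,
        branches=tuple(branches),
        true_angles=tuple(angles),
        unit=unit,
        plant_id=plant_id,
    )


def make_y_skeleton(
    angle_deg: float = 45.0,
    height: float = 20.0,
    attach_frac: float = 0.5,
    branch_length: float = 8.0,
    azimuth_deg: float = 0.0,
    stem_radius: float = 0.25,
    branch_radius: float = 0.2,
    plant_id: str = "y-fixture",
) -> GroundTruthSkeleton:
    """Deterministic straight-stem 'Y': one branch at an exact angle.

    Handy as an analytically known fixture: the stem is perfectly vertical,
    so the branch leaves the known node at exactly ``angle_deg``.
    """
    attach_z = attach_frac * height
    u_stem = np.array([0.0, 0.0, 1.0])
    phi = math.radians(azimuth_deg)
    w = np.array([math.cos(phi), math.sin(phi), 0.0])
    theta = math.radians(angle_deg)
    direction = math.cos(theta) * u_stem + math.sin(theta) * w
    branch = Branch(
        np.array([0.0, 0.0, attach_z]), direction, branch_length, branch_radius, u_stem
    )
    polyline = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, height]])
    return GroundTruthSkeleton(
        stem_polyline=polyline,
        stem_radius=stem_radius,
        branches=(branch,),
        true_angles=(angle_between_deg(direction, u_stem),),
        plant_id=plant_id,
    )


# ---------------------------------------------------------------------------
# surface sampling
# ---------------------------------------------------------------------------

def _frame(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors orthogonal to ``axis`` (deterministic)."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, axis)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    n1 = np.cross(axis, ref)
    n1 /= np.linalg.norm(n1)
    n2 = np.cross(axis, n1)
    return n1, n2


def _sample_cylinder(polyline: np.ndarray, radius: float, spacing: float) -> np.ndarray:
    """Points on the lateral surface of a tube around a polyline.

    Rings are placed every ``spacing`` of arclength along the whole curve
    (no duplicated rings at polyline joints), each with ``~2*pi*r/spacing``
    points so the surface grid is isotropic.
    """
    poly = np.asarray(polyline, dtype=float)
    seg = np.diff(poly, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    keep = seg_len > 0
    seg, seg_len = seg[keep], seg_len[keep]
    starts = poly[:-1][keep]
    total = float(seg_len.sum())
    if total == 0:
        return np.empty((0, 3))
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    n_rings = max(2, int(math.floor(total / spacing)) + 1)
    s_vals = np.linspace(0.0, total, n_rings)
    k = max(3, int(round(2.0 * math.pi * radius / spacing)))
    alpha = 2.0 * math.pi * np.arange(k) / k
    cos_a, sin_a = np.cos(alpha), np.sin(alpha)
    out = np.empty((n_rings * k, 3))
    seg_i = np.clip(np.searchsorted(cum, s_vals, side="right") - 1, 0, len(seg) - 1)
    for r, (s, i) in enumerate(zip(s_vals, seg_i)):
        t = (s - cum[i]) / seg_len[i]
        center = starts[i] + t * seg[i]
        axis = seg[i] / seg_len[i]
        n1, n2 = _frame(axis)
        out[r * k:(r + 1) * k] = center + radius * (
            cos_a[:, None] * n1 + sin_a[:, None] * n2
        )
    return out


def sample_cloud(
    skeleton: GroundTruthSkeleton, spec: SamplingSpec = SamplingSpec()
) -> tuple[PointCloud, dict]:
    """Sample the skeleton's cylinder surfaces into a cloud plus truth sidecar."""
    rng = np.random.default_rng(spec.seed)
    parts = [_sample_cylinder(skeleton.stem_polyline, skeleton.stem_radius, spec.spacing)]
    for br in skeleton.branches:
        pts = _sample_cylinder(
            np.vstack([br.attach_point, br.attach_point + br.direction * br.length]),
            br.radius,
            spec.spacing,
        )
        if spec.dropout > 0 and len(pts):
            keep = rng.random(len(pts)) >= spec.dropout
            pts = pts[keep]
        parts.append(pts)
    points = np.concatenate([p for p in parts if len(p)], axis=0)
    if spec.jitter_sd > 0:
        points = points + rng.normal(0.0, spec.jitter_sd, size=points.shape)
    if spec.n_outliers > 0:
        lo = points.min(axis=0) - 2.0
        hi = points.max(axis=0) + 2.0
        points = np.concatenate(
            [points, rng.uniform(lo, hi, size=(spec.n_outliers, 3))], axis=0
        )
    cloud = PointCloud(points, plant_id=skeleton.plant_id, unit=skeleton.unit)
    truth = {
        "plant_id": skeleton.plant_id,
        "unit": skeleton.unit,
        "nodes": [list(map(float, b.attach_point)) for b in skeleton.branches],
        "angles_deg": [float(a) for a in skeleton.true_angles],
    }
    return cloud, truth


# ---------------------------------------------------------------------------
# complexity-group fixture suites
# ---------------------------------------------------------------------------

#: repository conventions for the simple/medium/complex split: branch count
#: range, branch-angle range (degrees) and per-branch dropout fraction
GROUP_SPECS = {
    "simple": {"n_branches": (1, 2), "angle_range": (20.0, 50.0), "dropout": 0.0},
    "medium": {"n_branches": (3, 5), "angle_range": (20.0, 70.0), "dropout": 0.0},
    "complex": {"n_branches": (6, 9), "angle_range": (20.0, 90.0), "dropout": 0.10},
}


def make_fixture_suite(
    group: str, n: int, seed: int = 0, spacing: float = 0.2
) -> list[tuple[PointCloud, dict]]:
    """Generate ``n`` ground-truthed plants of one complexity group.

    Heights are uniform in 40-80 cm; every plant is fully determined by
    ``(group, n, seed)``.
    """
    if group not in GROUP_SPECS:
        raise ValueError(f"group must be one of {sorted(GROUP_SPECS)}")
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = GROUP_SPECS[group]
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        nb = int(rng.integers(cfg["n_branches"][0], cfg["n_branches"][1] + 1))
        height = float(rng.uniform(40.0, 80.0))
        skel_seed = int(rng.integers(0, 2**31 - 1))
        samp_seed = int(rng.integers(0, 2**31 - 1))
        skel = make_skeleton(
            nb, cfg["angle_range"], height, seed=skel_seed,
            plant_id=f"{group}_{i:02d}",
        )
        spec = SamplingSpec(spacing=spacing, dropout=cfg["dropout"], seed=samp_seed)
        out.append(sample_cloud(skel, spec))
    return out


def write_truth(truth: dict, path: str | os.PathLike) -> None:
    with open(os.fspath(path), "w") as fh:
        json.dump(truth, fh, indent=1)


def read_truth(path: str | os.PathLike) -> dict:
    with open(os.fspath(path)) as fh:
        return json.load(fh)
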