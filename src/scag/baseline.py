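"""Density-threshold (DB) baseline node detector.

The baseline rests on the observation that the local point density at a
stem-branch junction is higher than elsewhere on the plant: two cylinder
surfaces meet there, so a fixed-radius ball holds roughly twice the points.
Points whose neighbour count exceeds a percentile threshold are kept and
spatially clustered; each cluster's robust center is a candidate node.
Candidates feed the same branch-point optimization and angle calculation as
the main detector.

Density-threshold detectors of this kind leave the density statistic and
its calibration open; radius counts with a 95th-percentile cut are this
repository's defaults.
"""

from __future__ import annotations

import logging
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN

from .core import OptimizationError, ScagParams, branch_angle, optimize_branch_points
from .geometry import geometric_median
from .io import AngleRecord, PointCloud

logger = logging.getLogger("scag")

__all__ = ["density_field", "detect_nodes_density", "run_db"]


def density_field(cloud: PointCloud, rho: float) -> np.ndarray:
    """Per-point neighbour count within radius ``rho`` (self included)."""
    if rho <= 0:
        raise ValueError("rho must be positive")
    tree = cKDTree(cloud.points)
    return np.array([len(ix) for ix in tree.query_ball_point(cloud.points, rho)])


def detect_nodes_density(
    cloud: PointCloud, rho: float = 1.0, percentile: float = 95.0
) -> list[np.ndarray]:
    """Candidate node points from the high-density tail of the cloud.

    Keeps points at or above the given percentile of the neighbour-count
    distribution, groups them with DBSCAN (eps = rho) and returns one robust
    center per group.  May legitimately return an empty list.
    """
    if not (0 < percentile <= 100):
        raise ValueError("percentile must be in (0, 100]")
    if len(cloud) <= 10:
        raise ValueError("density baseline needs more than 10 points")
    counts = density_field(cloud, rho)
    thresh = np.percentile(counts, percentile)
    kept = np.flatnonzero(counts >= thresh)
    if len(kept) == 0:
        return []
    labels = DBSCAN(eps=rho, min_samples=1).fit_predict(cloud.points[kept])
    nodes = []
    for lab in sorted(set(labels)):
        rows = kept[labels == lab]
        nodes.append(geometric_median(cloud.points[rows]))
    return nodes


def run_db(
    cloud: PointCloud,
    params: Optional[ScagParams] = None,
    rho: float = 1.0,
    percentile: float = 95.0,
) -> list[AngleRecord]:
    """Full baseline pipeline: density nodes + shared angle calculation."""
    if params is None:
        params = ScagParams.for_unit(cloud.unit)
    records = []
    for node in detect_nodes_density(cloud, rho=rho, percentile=percentile):
        try:
            p1, p2 = optimize_branch_points(cloud.points, node, params)
        except OptimizationError as exc:
            logger.warning("%s: DB node at z=%.2f: %s", cloud.plant_id, node[2], exc)
            continue
        try:
            ang = branch_angle(node, p1, p2)
        except ValueError:
            continue
        if not (0.0 < ang < 180.0):
            continue
        records.append(
            AngleRecord(
                node_point=node, branch_point_1=p1, branch_point_2=p2,
                angle_deg=ang, plant_id=cloud.plant_id,
            )
        )
    return records
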