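"""Low-level geometric primitives shared across the pipeline.

The robust cluster/node center used throughout is the geometric median
(Weiszfeld's algorithm).  Like the per-axis median it is insensitive to
outlying points, but unlike it the geometric median is exactly equivariant
under rigid motions, which the detection pipeline relies on: rotating or
translating a plant cloud must move every detected node point consistently
and leave branch angles unchanged.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "geometric_median",
    "angle_between_deg",
    "principal_direction",
    "knn_indices",
    "rotate_z",
]


def geometric_median(points: np.ndarray, tol: float = 1e-10, max_iter: int = 200) -> np.ndarray:
    """Geometric median of an (n, d) point set via Weiszfeld iteration.

    The convergence tolerance is relative to the spread of the set, so the
    result is scale-equivariant to floating-point precision.  A point that
    coincides with the current iterate is handled with the standard
    Vardi-Zhang correction.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or len(pts) == 0:
        raise ValueError("geometric_median requires a non-empty (n, d) array")
    if len(pts) == 1:
        return pts[0].copy()
    if len(pts) == 2:
        return 0.5 * (pts[0] + pts[1])

    scale = float(np.max(np.ptp(pts, axis=0)))
    if scale == 0.0:  # all points identical
        return pts[0].copy()
    atol = tol * scale

    y = np.median(pts, axis=0)  # warm start at the componentwise median
    for _ in range(max_iter):
        d = np.linalg.norm(pts - y, axis=1)
        coincident = d < atol
        if np.any(coincident):
            d = np.where(coincident, np.inf, d)
        w = 1.0 / d
        sw = w.sum()
        if not np.isfinite(sw) or sw == 0.0:
            return y
        t = (pts * w[:, None]).sum(axis=0) / sw
        n_co = int(np.count_nonzero(coincident))
        if n_co:
            # Vardi-Zhang step when the iterate sits on a data point.
            r = float(np.linalg.norm(((pts - y) * w[:, None]).sum(axis=0)))
            if r <= n_co:
                return y
            t = (1.0 - n_co / r) * t + (n_co / r) * y
        if np.linalg.norm(t - y) < atol:
            return t
        y = t
    return y


def angle_between_deg(a: np.ndarray, b: np.ndarray) -> float:
    """Angle between two nonzero vectors, in degrees, in [0, 180].

    Computed as atan2(|a x b|, a . b) — algebraically the clamped-arccos of
    the normalized dot product, but numerically exact for (anti)parallel
    vectors where arccos loses ~1e-6 degrees.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.linalg.norm(a) == 0.0 or np.linalg.norm(b) == 0.0:
        raise ValueError("angle undefined for a zero-length vector")
    cross = float(np.linalg.norm(np.cross(a, b)))
    dot = float(np.dot(a, b))
    return float(np.degrees(np.arctan2(cross, dot)))


def principal_direction(points: np.ndarray) -> np.ndarray:
    """Unit first principal axis of a point set (sign unspecified)."""
    pts = np.asarray(points, dtype=float)
    centered = pts - pts.mean(axis=0)
    # SVD of the centered set; right singular vector of largest singular value
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    v = vt[0]
    n = np.linalg.norm(v)
    return v / n if n > 0 else v


def knn_indices(points: np.ndarray, query: np.ndarray, k: int, tie_rtol: float = 1e-9) -> np.ndarray:
    """Indices of the k nearest points to ``query``, ties included.

    All points whose distance is within ``tie_rtol`` (relative) of the k-th
    distance are returned, so the selected *set* does not depend on how an
    exact tie happens to be ordered — a requirement for rigid-motion
    reproducibility on regularly sampled clouds.
    """
    pts = np.asarray(points, dtype=float)
    if k <= 0:
        raise ValueError("k must be positive")
    if len(pts) < k:
        raise ValueError(f"need at least k={k} points, got {len(pts)}")
    d2 = np.einsum("ij,ij->i", pts - query, pts - query)
    if len(pts) == k:
        return np.arange(len(pts))
    part = np.argpartition(d2, k - 1)
    kth = d2[part[k - 1]]
    cut = kth * (1.0 + tie_rtol) + 1e-300
    return np.flatnonzero(d2 <= cut)


def rotate_z(points: np.ndarray, angle_deg: float) -> np.ndarray:
    """Rotate an (n, 3) point set about the z axis."""
    t = np.radians(angle_deg)
    c, s = np.cos(t), np.sin(t)
    rot = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    return np.asarray(points, dtype=float) @ rot.T
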