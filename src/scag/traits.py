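"""Plant-architecture traits, composite density-tolerance indices, and the
screening statistics (replicate filtering, min-max scaling, DTW
repeatability, broad-sense heritability).

Basic traits per plant
----------------------
height        z extent of the cloud
canopy_width  maximum pairwise distance between xy-projected points
stem_length   polyline length through per-layer stem-cluster centers,
              chained upward from the base (posture-robust, unlike height)
average_angle mean of the detected branch angles (degrees)
angle_number  number of detected branches
npd           mean nearest-point distance (sampling density diagnostic)

Composite indices
-----------------
Ten ratios/products of the basic traits (CHR, CLR, LHR, CAR, AHR, ALR, ANR,
ACHR, ACLR, ANRCHR); smaller values describe more compact plants, the
architecture favoured for dense planting.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from scipy.spatial.distance import pdist

from .core import ScagParams, cluster_layer, stratify
from .io import AngleRecord, PointCloud

logger = logging.getLogger("scag")

__all__ = [
    "TraitRow", "DTWResult", "HeritabilityResult",
    "basic_traits", "composite_indices", "filter_varieties",
    "minmax_normalize", "dtw_distance", "dtw_repeatability", "heritability",
    "INDEX_NAMES",
]

INDEX_NAMES = (
    "CHR", "CLR", "LHR", "CAR", "AHR", "ALR", "ANR", "ACHR", "ACLR", "ANRCHR",
)


@dataclass
class TraitRow:
    """Basic traits of one plant, with experimental-design labels."""

    height: float
    canopy_width: float
    stem_length: float
    average_angle: float
    angle_number: int
    npd: float
    variety: str = ""
    replicate: int = 0
    year: int = 0
    plant_id: str = ""


@dataclass(frozen=True)
class DTWResult:
    distance: float
    path: tuple  # monotone index pairs from (0, 0) to (n-1, m-1)


@dataclass(frozen=True)
class HeritabilityResult:
    H2: float
    sigma2_g: float
    sigma2_e: float
    n_varieties: int
    n_total: int


# ---------------------------------------------------------------------------
# per-plant traits
# ---------------------------------------------------------------------------

def _canopy_width(points: np.ndarray) -> float:
    """Maximum pairwise xy distance (diameter of the projected canopy)."""
    xy = points[:, :2]
    if len(xy) < 2:
        return 0.0
    if len(xy) > 2000:
        # diameter is attained on the convex hull; fall back if degenerate
        try:
            from scipy.spatial import ConvexHull

            xy = xy[ConvexHull(xy, qhull_options="QJ").vertices]
        except Exception:  # collinear input etc.
            pass
    return float(np.max(pdist(xy)))


def _stem_polyline_length(cloud: PointCloud, params: ScagParams) -> float:
    """Stem length by chaining per-layer stem clusters from the base upward.

    In each layer the chain continues to the cluster nearest the previous
    center; the run is closed with vertical extensions to the base and the
    chain top so a straight stem of height h measures ~h.
    """
    layers = stratify(cloud, params.H)
    centers = []
    prev = None
    reached_top = True
    for ly in layers:
        if ly.is_empty:
            continue
        clusters = cluster_layer(
            cloud.points[ly.member_indices], params.eps, params.min_samples
        )
        if not clusters:
            continue
        if prev is None:
            # base cluster: the one holding the lowest point of the layer
            low_local = int(np.argmin(cloud.points[ly.member_indices][:, 2]))
            pick = next(
                (c for c in clusters if low_local in set(np.asarray(c.member_indices).tolist())),
                clusters[0],
            )
        else:
            d = [float(np.linalg.norm(c.median_point - prev)) for c in clusters]
            pick = clusters[int(np.argmin(d))]
            if d[int(np.argmin(d))] > 3.0 * params.H:
                reached_top = False
                break  # chain lost (gap or detached structure)
        centers.append(pick.median_point)
        prev = pick.median_point
    if not centers:
        return cloud.z_extent
    centers = np.asarray(centers)
    seg = float(np.sum(np.linalg.norm(np.diff(centers, axis=0), axis=1)))
    bottom_ext = max(float(centers[0, 2] - cloud.z.min()), 0.0)
    top_ext = max(float(cloud.z.max() - centers[-1, 2]), 0.0) if reached_top else 0.0
    return seg + bottom_ext + top_ext


def basic_traits(
    cloud: PointCloud,
    records: Sequence[AngleRecord],
    params: Optional[ScagParams] = None,
    **labels,
) -> TraitRow:
    """Basic 3D traits of one plant from its cloud and detected branches."""
    if params is None:
        params = ScagParams.for_unit(cloud.unit)
    pts = cloud.points
    height = cloud.z_extent
    width = _canopy_width(pts)
    stem_len = _stem_polyline_length(cloud, params)
    angles = [r.angle_deg for r in records]
    avg = float(np.mean(angles)) if angles else float("nan")
    if len(pts) >= 2:
        d, _ = cKDTree(pts).query(pts, k=2)
        npd = float(np.mean(d[:, 1]))
    else:
        npd = float("nan")
    return TraitRow(
        height=height, canopy_width=width, stem_length=stem_len,
        average_angle=avg, angle_number=len(angles), npd=npd,
        plant_id=cloud.plant_id, **labels,
    )


def composite_indices(row: TraitRow) -> dict:
    """The ten composite density-tolerance indices of one plant.

    NaN propagates from undefined inputs; a zero denominator yields NaN
    with a warning.
    """
    def ratio(num, den, name):
        if any(map(_isnan, (num, den))):
            return float("nan")
        if den == 0:
            warnings.warn(f"{name}: zero denominator", RuntimeWarning, stacklevel=3)
            return float("nan")
        return num / den

    chr_ = ratio(row.canopy_width, row.height, "CHR")
    clr = ratio(row.canopy_width, row.stem_length, "CLR")
    lhr = ratio(row.stem_length, row.height, "LHR")
    car = ratio(row.canopy_width, row.average_angle, "CAR")
    ahr = ratio(row.average_angle, row.height, "AHR")
    alr = ratio(row.average_angle, row.stem_length, "ALR")
    anr = ratio(row.average_angle, row.angle_number, "ANR")
    mul = lambda a, b: float("nan") if any(map(_isnan, (a, b))) else a * b
    return {
        "CHR": chr_, "CLR": clr, "LHR": lhr, "CAR": car, "AHR": ahr,
        "ALR": alr, "ANR": anr,
        "ACHR": mul(row.average_angle, chr_),
        "ACLR": mul(row.average_angle, clr),
        "ANRCHR": mul(anr, chr_),
    }


def _isnan(x) -> bool:
    try:
        return math.isnan(float(x))
    except (TypeError, ValueError):
        return True


# ---------------------------------------------------------------------------
# screening statistics
# ---------------------------------------------------------------------------

def filter_varieties(table: pd.DataFrame, threshold: float = 0.30) -> pd.DataFrame:
    """Replicate-consistency filter on a trait table.

    A variety is dropped when (i) any (year, replicate) cell of the full
    design has no sample for it, or (ii) within any year the relative error
    of stem length between the two replicates, |a - b| / mean(a, b), exceeds
    the threshold.  Stem length anchors the check because it is accurate and
    insensitive to plant posture.
    """
    required = {"variety", "replicate", "year", "stem_length"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"trait table lacks columns {sorted(missing)}")
    cells = [
        (y, r)
        for y in sorted(table["year"].unique())
        for r in sorted(table["replicate"].unique())
    ]
    keep = []
    for variety, grp in table.groupby("variety"):
        present = set(zip(grp["year"], grp["replicate"]))
        if any(c not in present for c in cells):
            continue
        ok = True
        for year, g in grp.groupby("year"):
            reps = g.groupby("replicate")["stem_length"].mean().to_numpy()
            if len(reps) >= 2:
                a, b = reps[:2]
                m = 0.5 * (a + b)
                if m == 0 or abs(a - b) / m > threshold:
                    ok = False
                    break
        if ok:
            keep.append(variety)
    return table[table["variety"].isin(keep)].reset_index(drop=True)


def minmax_normalize(series: Sequence[float]) -> np.ndarray:
    """Scale to [0, 1]: (x - min) / (max - min).  Constant input is an error."""
    x = np.asarray(series, dtype=float)
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)


def dtw_distance(s1: Sequence[float], s2: Sequence[float]) -> DTWResult:
    """Classic dynamic-time-warping distance with absolute-difference cost.

    Unconstrained window, no path-length normalization; returns the optimal
    monotone alignment path from (0, 0) to (n-1, m-1).  Smaller distance
    means better agreement of the two profiles.
    """
    a = np.asarray(s1, dtype=float)
    b = np.asarray(s2, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("sequences must be nonempty")
    n, m = len(a), len(b)
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n, m), np.inf)
    acc[0, 0] = cost[0, 0]
    for i in range(n):
        for j in range(m):
            if i == j == 0:
                continue
            best = np.inf
            if i > 0:
                best = min(best, acc[i - 1, j])
            if j > 0:
                best = min(best, acc[i, j - 1])
            if i > 0 and j > 0:
                best = min(best, acc[i - 1, j - 1])
            acc[i, j] = cost[i, j] + best
    # backtrack
    path = [(n - 1, m - 1)]
    i, j = n - 1, m - 1
    while (i, j) != (0, 0):
        steps = []
        if i > 0 and j > 0:
            steps.append((acc[i - 1, j - 1], (i - 1, j - 1)))
        if i > 0:
            steps.append((acc[i - 1, j], (i - 1, j)))
        if j > 0:
            steps.append((acc[i, j - 1], (i, j - 1)))
        i, j = min(steps, key=lambda t: t[0])[1]
        path.append((i, j))
    return DTWResult(float(acc[n - 1, m - 1]), tuple(reversed(path)))


def dtw_repeatability(
    year_a: pd.DataFrame,
    year_b: pd.DataFrame,
    traits: Sequence[str],
    mode: str = "normalized",
) -> pd.Series:
    """Cross-year DTW per trait over a common, fixed variety order.

    ``mode='normalized'`` warps the min-max-scaled trait values;
    ``mode='rank'`` warps the variety ranks instead.  Both tables must be
    indexed (or indexable) by variety; only shared varieties are compared,
    in sorted order, so every trait sees the same sequence order.
    """
    if mode not in ("normalized", "rank"):
        raise ValueError("mode must be 'normalized' or 'rank'")
    a = year_a.set_index("variety") if "variety" in year_a.columns else year_a
    b = year_b.set_index("variety") if "variety" in year_b.columns else year_b
    common = sorted(set(a.index) & set(b.index))
    if not common:
        raise ValueError("no shared varieties between years")
    out = {}
    for trait in traits:
        sa = a.loc[common, trait].astype(float).to_numpy()
        sb = b.loc[common, trait].astype(float).to_numpy()
        if mode == "rank":
            sa = pd.Series(sa).rank().to_numpy()
            sb = pd.Series(sb).rank().to_numpy()
        else:
            sa = minmax_normalize(sa)
            sb = minmax_normalize(sb)
        out[trait] = dtw_distance(sa, sb).distance
    return pd.Series(out, name=f"DTW_{mode}")


def heritability(values) -> HeritabilityResult:
    """Broad-sense heritability on an entry-mean basis.

    ``values`` is a variety-by-replicate table (2D array or DataFrame with
    varieties as rows; NaN marks missing replicates).  A one-way
    random-effects decomposition with variety as the grouping factor gives

        sigma2_e = MS_within,
        sigma2_g = (MS_between - MS_within) / n0   (truncated at 0),
        H2 = sigma2_g / (sigma2_g + sigma2_e / n_rep),

    where n0 is the effective replicate number for (possibly) unbalanced
    data and n_rep the mean replicate count.
    """
    if isinstance(values, pd.DataFrame):
        arr = values.to_numpy(dtype=float)
    else:
        arr = np.asarray(values, dtype=float)
    if arr.ndim != 2:
        raise ValueError("values must be a 2D variety x replicate table")
    groups = [row[~np.isnan(row)] for row in arr]
    groups = [g for g in groups if len(g) > 0]
    a = len(groups)
    if a < 2:
        raise ValueError("need at least 2 varieties with data")
    sizes = np.array([len(g) for g in groups], dtype=float)
    N = float(sizes.sum())
    if N - a <= 0:
        raise ValueError("need replicated varieties to estimate residual variance")
    means = np.array([np.mean(g) for g in groups])
    grand = float(np.concatenate(groups).mean())
    ss_between = float(np.sum(sizes * (means - grand) ** 2))
    ss_within = float(sum(np.sum((g - m) ** 2) for g, m in zip(groups, means)))
    ms_between = ss_between / (a - 1)
    ms_within = ss_within / (N - a)
    n0 = (N - float(np.sum(sizes**2)) / N) / (a - 1)
    sigma_g = max(0.0, (ms_between - ms_within) / n0)
    sigma_e = ms_within
    n_rep = N / a
    denom = sigma_g + sigma_e / n_rep
    h2 = 0.0 if denom == 0 else sigma_g / denom
    return HeritabilityResult(
        H2=float(min(max(h2, 0.0), 1.0)),
        sigma2_g=sigma_g,
        sigma2_e=sigma_e,
        n_varieties=a,
        n_total=int(N),
    )
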