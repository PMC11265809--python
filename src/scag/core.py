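"""The SCAG branch detector.

The pipeline mirrors how a field scientist reads a defoliated plant from the
bottom up:

1. *Stratify* the cloud into horizontal layers of height ``H`` and cluster
   each layer with DBSCAN; every cluster is summarised by a robust center.
2. *Detect branch layers* by comparing cluster counts between adjacent
   layers.  A layer gains a new branch when the count increases (case 1) or,
   at equal/decreasing counts (cases 2-3), when the nearest-cluster distance
   pattern between the layers breaks the "twice the minimum" rule.
3. *Locate the node* (stem-branch junction) by downward region growing: the
   two closest clusters of a branch layer seed an iterative search in which
   each seed is replaced by the robust center of its ``N`` nearest
   neighbours, after discarding all points above the seeds.  Growth stops
   when the two neighbourhoods overlap substantially; the overlap's center
   is the node point.
4. *Optimize branch points* by cutting a thin slice a distance ``D`` above
   the node, splitting it into a stem group and a branch group, and taking
   each group's center; the branch angle is the angle at the node between
   the two center directions.

All length parameters are interpreted in the cloud's declared unit; the
stated defaults are in centimetres and are rescaled by
:meth:`ScagParams.for_unit`.  The algorithm contains no randomness.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from sklearn.cluster import DBSCAN

from .geometry import angle_between_deg, geometric_median, knn_indices, principal_direction
from .io import AngleRecord, PointCloud, UNIT_TO_CM

logger = logging.getLogger("scag")

__all__ = [
    "ScagParams", "Layer", "ClusterRef", "AdjacencyDecision", "NodeResult",
    "GrowthError", "OptimizationError", "SelectionError",
    "stratify", "cluster_layer", "detect_branch_layers", "select_branch_pair",
    "locate_node", "optimize_branch_points", "branch_angle",
    "detect_nodes", "run_scag",
]

#: relative nudge used when binning z values into layers so that points
#: sitting exactly on a layer boundary land consistently after translation
_EDGE_TOL = 1e-9


class GrowthError(RuntimeError):
    """Downward growth could not run (cropped cloud smaller than N)."""


class OptimizationError(RuntimeError):
    """The optimization slice could not be split into two groups."""


class SelectionError(ValueError):
    """A branch layer did not contain two clusters to pair."""


@dataclass(frozen=True)
class ScagParams:
    """Tunable parameters, in the length unit of the cloud they are applied to.

    Defaults are stated in centimetres: slice height ``H`` of about twice the
    branch diameter, growth point number ``N`` in the insensitive 20-140
    range, slice depth ``D`` in the 2-3 cm optimum, DBSCAN reach ``eps`` of
    2.5x the ~2 mm scan spacing.
    """

    H: float = 1.0
    N: int = 60
    D: float = 2.5
    eps: float = 0.5
    min_samples: int = 5
    merge_radius: float = 1.0
    max_growth_iters: int = 100
    overlap_fraction: float = 0.5
    ratio_multiplier: float = 2.0
    opt_thickness: float = 1.0
    min_dist_floor: float = 1e-9
    refine: bool = True
    refine_slab: float = 3.0

    #: fields that denote lengths and must be rescaled with the cloud unit
    _LENGTH_FIELDS = ("H", "D", "eps", "merge_radius", "opt_thickness", "refine_slab")

    def __post_init__(self):
        if self.H <= 0 or self.D <= 0 or self.eps <= 0:
            raise ValueError("H, D and eps must be positive")
        if self.N < 2:
            raise ValueError("N must be >= 2")
        if self.min_samples < 1:
            raise ValueError("min_samples must be >= 1")
        if self.merge_radius < 0:
            raise ValueError("merge_radius must be >= 0")
        if self.max_growth_iters < 1:
            raise ValueError("max_growth_iters must be >= 1")
        if not (0 < self.overlap_fraction <= 1):
            raise ValueError("overlap_fraction must be in (0, 1]")

    @classmethod
    def for_unit(cls, unit: str, **overrides) -> "ScagParams":
        """Defaults (stated in cm) rescaled to ``unit``; overrides are in ``unit``."""
        factor = 1.0 / UNIT_TO_CM[unit]
        base = cls()
        scaled = {f: getattr(base, f) * factor for f in cls._LENGTH_FIELDS}
        scaled.update(overrides)
        return cls(**scaled)

    def scaled(self, factor: float) -> "ScagParams":
        """All length parameters multiplied by ``factor`` (unit change)."""
        return replace(self, **{f: getattr(self, f) * factor for f in self._LENGTH_FIELDS})


@dataclass(frozen=True)
class Layer:
    """One horizontal slice of the cloud."""

    index: int
    z_lo: float
    z_hi: float
    member_indices: np.ndarray

    @property
    def is_empty(self) -> bool:
        return len(self.member_indices) == 0


@dataclass(frozen=True)
class ClusterRef:
    """A DBSCAN cluster within a layer, summarised by its robust center."""

    layer_index: int
    member_indices: np.ndarray
    median_point: np.ndarray


@dataclass(frozen=True)
class AdjacencyDecision:
    """Outcome of comparing one pair of adjacent (non-empty) layers."""

    lower_layer: int
    upper_layer: int
    CNL: int
    CNU: int
    D_CNL: tuple
    Nmin: int
    case: int
    new_branch: bool


@dataclass(frozen=True)
class NodeResult:
    """A located stem-branch junction."""

    node_point: np.ndarray
    iterations: int
    overlap_size: int
    degraded: bool


# ---------------------------------------------------------------------------
# step 0: stratification
# ---------------------------------------------------------------------------

def stratify(cloud: PointCloud, H: float) -> list[Layer]:
    """Slice the cloud into layers of height ``H`` from the base upward.

    Layers are half-open ``[z_lo, z_hi)`` with the topmost closed; the
    topmost layer may be shorter than ``H``.  Empty layers are kept so that
    layer indices map directly to heights.
    """
    if H <= 0:
        raise ValueError("H must be positive")
    z = cloud.z
    z_min = float(z.min())
    z_max = float(z.max())
    extent = z_max - z_min
    n_layers = max(1, int(math.ceil(extent / H - _EDGE_TOL)))
    # nudge keeps boundary points stable under rigid translation of the cloud
    idx = np.floor((z - z_min) / H + _EDGE_TOL).astype(int)
    np.clip(idx, 0, n_layers - 1, out=idx)
    layers = []
    for i in range(n_layers):
        lo = z_min + i * H
        hi = z_max if i == n_layers - 1 else z_min + (i + 1) * H
        layers.append(Layer(i, lo, hi, np.flatnonzero(idx == i)))
    return layers


# ---------------------------------------------------------------------------
# step 1: per-layer clustering
# ---------------------------------------------------------------------------

def cluster_layer(
    points: np.ndarray,
    eps: float,
    min_samples: int,
    layer_index: int = 0,
    member_indices: Optional[np.ndarray] = None,
) -> list[ClusterRef]:
    """DBSCAN-cluster the points of one layer in full 3D.

    Noise points belong to no cluster.  ``member_indices`` maps layer-local
    rows back to cloud-global indices in the returned clusters.
    """
    pts = np.asarray(points, dtype=float)
    if len(pts) == 0:
        return []
    if member_indices is None:
        member_indices = np.arange(len(pts))
    labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pts)
    clusters = []
    for lab in sorted(set(labels) - {-1}):
        rows = np.flatnonzero(labels == lab)
        clusters.append(
            ClusterRef(
                layer_index=layer_index,
                member_indices=np.asarray(member_indices)[rows],
                median_point=geometric_median(pts[rows]),
            )
        )
    return clusters


# ---------------------------------------------------------------------------
# step 2: branch-layer detection (cases 1-3)
# ---------------------------------------------------------------------------

def _decide_pair(
    lower: Sequence[ClusterRef],
    upper: Sequence[ClusterRef],
    ratio_multiplier: float,
    min_dist_floor: float,
) -> tuple[tuple, int, int, bool]:
    """Nearest-cluster distances, Nmin, case id and the new-branch verdict."""
    up_centers = np.array([c.median_point for c in upper])
    d_cnl = tuple(
        float(np.min(np.linalg.norm(up_centers - c.median_point, axis=1))) for c in lower
    )
    cnl, cnu = len(lower), len(upper)
    dmin = max(min(d_cnl), min_dist_floor)
    nmin = sum(1 for d in d_cnl if d < ratio_multiplier * dmin)
    if cnu > cnl:
        return d_cnl, nmin, 1, True
    if cnu == cnl:
        return d_cnl, nmin, 2, max(d_cnl) > ratio_multiplier * dmin
    return d_cnl, nmin, 3, nmin < cnu


def detect_branch_layers(
    clusters_per_layer: Sequence[Sequence[ClusterRef]],
    ratio_multiplier: float = 2.0,
    min_dist_floor: float = 1e-9,
) -> list[AdjacencyDecision]:
    """Compare adjacent layers bottom-to-top and flag layers holding new branches.

    Layers without clusters are skipped: each clustered layer is compared
    with the nearest clustered layer below it, so sparse slices do not break
    the vertical continuity of the plant.
    """
    occupied = [i for i, cl in enumerate(clusters_per_layer) if len(cl) > 0]
    decisions = []
    for lo_i, up_i in zip(occupied[:-1], occupied[1:]):
        lower, upper = clusters_per_layer[lo_i], clusters_per_layer[up_i]
        d_cnl, nmin, case, new = _decide_pair(lower, upper, ratio_multiplier, min_dist_floor)
        decisions.append(
            AdjacencyDecision(
                lower_layer=lo_i, upper_layer=up_i,
                CNL=len(lower), CNU=len(upper),
                D_CNL=d_cnl, Nmin=nmin, case=case, new_branch=new,
            )
        )
    return decisions


def _pair_for_branch(
    lower: Sequence[ClusterRef], upper: Sequence[ClusterRef]
) -> tuple[ClusterRef, ClusterRef]:
    """Seed pair for a retained branch layer: (source structure, new branch).

    Upper clusters claim their nearest lower cluster greedily in ascending
    distance order; a continuation always wins its own lower cluster, so an
    upper cluster whose nearest lower is already claimed is the newly split
    branch, and the claimant of that lower cluster is the structure it split
    from.  Falls back to the closest-pair rule when every upper cluster
    found an unclaimed source (distance alone cannot tell a steep
    continuation from a fresh split).
    """
    if len(upper) < 2:
        raise SelectionError("branch layer needs at least 2 clusters")
    if not lower:
        return select_branch_pair(upper)
    low_centers = np.array([c.median_point for c in lower])
    nearest = []
    for c in upper:
        d = np.linalg.norm(low_centers - c.median_point, axis=1)
        nearest.append((float(d.min()), int(d.argmin())))
    order = sorted(range(len(upper)), key=lambda i: nearest[i][0])
    claimed: dict[int, int] = {}
    new_candidates = []
    for i in order:
        src = nearest[i][1]
        if src not in claimed:
            claimed[src] = i
        else:
            new_candidates.append(i)
    if not new_candidates:
        return select_branch_pair(upper)
    new_i = new_candidates[0]  # the closest-splitting new cluster
    partner = upper[claimed[nearest[new_i][1]]]
    return partner, upper[new_i]


def select_branch_pair(clusters: Sequence[ClusterRef]) -> tuple[ClusterRef, ClusterRef]:
    """The two clusters of a branch layer whose centers are closest.

    Ties are broken toward the lowest cluster indices, so the result is
    deterministic.
    """
    if len(clusters) < 2:
        raise SelectionError("branch layer needs at least 2 clusters")
    best = None
    best_d = np.inf
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            d = float(np.linalg.norm(clusters[i].median_point - clusters[j].median_point))
            if d < best_d:
                best_d, best = d, (clusters[i], clusters[j])
    return best


# ---------------------------------------------------------------------------
# step 3: node location by downward region growth
# ---------------------------------------------------------------------------

def locate_node(
    points: np.ndarray,
    seeds: tuple[np.ndarray, np.ndarray],
    params: ScagParams,
) -> NodeResult:
    """Grow two neighbourhoods downward from the seed pair until they meet.

    Each iteration (i) discards all points above the current seeds, (ii)
    replaces each seed by the robust center of its ``N`` nearest neighbours
    in what remains.  The removal step is what drives the seeds downhill
    toward the junction; repeating it with the updated seeds keeps them
    moving.  Growth terminates when the two neighbour sets share at least
    ``overlap_fraction * N`` points; the node is the robust center of the
    shared points.  Hitting the iteration cap marks the result degraded (the
    node falls back to the seed midpoint if the sets never met).
    """
    pts = np.asarray(points, dtype=float)
    s1 = np.asarray(seeds[0], dtype=float).copy()
    s2 = np.asarray(seeds[1], dtype=float).copy()
    need = int(math.ceil(params.overlap_fraction * params.N))
    overlap = np.empty(0, dtype=int)
    for it in range(1, params.max_growth_iters + 1):
        z_cap = max(s1[2], s2[2])
        keep = np.flatnonzero(pts[:, 2] <= z_cap * (1 + np.sign(z_cap) * 1e-12) + 1e-12)
        if len(keep) < params.N:
            raise GrowthError(
                f"cropped cloud has {len(keep)} points, fewer than N={params.N}"
            )
        sub = pts[keep]
        ia = keep[knn_indices(sub, s1, params.N)]
        ib = keep[knn_indices(sub, s2, params.N)]
        s1 = geometric_median(pts[ia])
        s2 = geometric_median(pts[ib])
        overlap = np.intersect1d(ia, ib, assume_unique=True)
        if len(overlap) >= need:
            return NodeResult(geometric_median(pts[overlap]), it, len(overlap), False)
    if len(overlap) > 0:
        return NodeResult(geometric_median(pts[overlap]), params.max_growth_iters, len(overlap), True)
    return NodeResult(0.5 * (s1 + s2), params.max_growth_iters, 0, True)


def _line_closest_point(c1, u1, c2, u2):
    """Midpoint and width of the common perpendicular between two 3D lines."""
    w0 = c1 - c2
    a = np.dot(u1, u1)
    b = np.dot(u1, u2)
    c = np.dot(u2, u2)
    d = np.dot(u1, w0)
    e = np.dot(u2, w0)
    denom = a * c - b * b
    if denom <= 1e-12:
        return None, np.inf
    s = (b * e - c * d) / denom
    t = (a * e - b * d) / denom
    p1 = c1 + s * u1
    p2 = c2 + t * u2
    return 0.5 * (p1 + p2), float(np.linalg.norm(p1 - p2))


def _chain_rows(
    clusters_per_layer: Sequence[Sequence[ClusterRef]],
    start_layer: int,
    start: ClusterRef,
    n_layers_up: int,
    max_jump: float,
    taken: set,
) -> list[np.ndarray]:
    """Follow a cluster upward layer by layer (nearest-center continuation).

    Stops at a missing continuation, a jump larger than ``max_jump``, a
    cluster already claimed by the other chain, or a sudden growth in
    cluster size — the chain must stay on one physical structure, and a
    size jump means the cluster has absorbed another branch emerging just
    above (its center no longer tracks this structure's axis).
    """
    rows = [np.asarray(start.member_indices)]
    taken.add((start_layer, id(start)))
    cur = start.median_point
    layer = start_layer
    for _ in range(n_layers_up):
        layer += 1
        if layer >= len(clusters_per_layer) or not clusters_per_layer[layer]:
            break
        cands = clusters_per_layer[layer]
        d = [float(np.linalg.norm(c.median_point - cur)) for c in cands]
        j = int(np.argmin(d))
        if d[j] > max_jump or (layer, id(cands[j])) in taken:
            break
        # first chain cluster is often clipped at the split layer, so the
        # size reference only becomes meaningful from two clusters on
        if len(rows) >= 2 and len(cands[j].member_indices) > 1.6 * np.median(
            [len(r) for r in rows]
        ):
            break
        taken.add((layer, id(cands[j])))
        rows.append(np.asarray(cands[j].member_indices))
        cur = cands[j].median_point
    return rows


def _fit_chain_axis(points: np.ndarray, rows: list, min_span: float, trim: float = 1.75):
    """Robust center + principal axis of a cluster chain, or None if stubby.

    After an initial fit, points whose perpendicular distance to the axis
    exceeds ``trim`` times the median distance are dropped and the axis is
    refit (twice).  On a clean cylinder every point sits near the surface
    radius so nothing is trimmed; a bulge from another branch merging into
    the chain sticks out several radii and is rejected, which keeps the
    axis from tilting toward it.
    """
    pts = points[np.concatenate(rows)]
    if np.ptp(pts[:, 2]) < min_span:
        return None
    c, u = geometric_median(pts), principal_direction(pts)
    for _ in range(2):
        rel = pts - c
        perp = rel - np.outer(rel @ u, u)
        d = np.linalg.norm(perp, axis=1)
        keep = d <= trim * max(float(np.median(d)), 1e-9)
        if keep.all() or keep.sum() < 10:
            break
        sub = pts[keep]
        if np.ptp(sub[:, 2]) < min_span:
            break
        pts = sub
        c, u = geometric_median(pts), principal_direction(pts)
    return c, u


@dataclass(frozen=True)
class JunctionAxes:
    """Fitted local directions at a junction, oriented away from the node."""

    stem_dir: np.ndarray
    branch_dir: np.ndarray

    @property
    def angle_deg(self) -> float:
        return angle_between_deg(self.stem_dir, self.branch_dir)


def refine_node(
    points: np.ndarray,
    prelim: np.ndarray,
    clusters_per_layer: Sequence[Sequence[ClusterRef]],
    branch_cluster: ClusterRef,
    partner_clusters: Sequence[ClusterRef],
    layer_index: int,
    params: ScagParams,
) -> tuple[np.ndarray, Optional[JunctionAxes]]:
    """Sharpen a preliminary node by intersecting local structure axes.

    The overlap-median node from downward growth sits where the two kNN
    neighbourhoods merge, which for shallow branch angles is above the
    physical junction (small angles are overestimated as a result).  This
    follows the new branch cluster and every other cluster of its layer
    upward as cluster chains, fits a principal axis to each chain, and
    replaces the node by the closest-approach midpoint between the branch
    axis and the partner axis it genuinely meets (minimal line-to-line
    gap) — the source structure's axis passes through the junction, while
    an unrelated branch's axis passes at a distance.  When no partner axis
    comes close, the chains are too short for a stable fit, the axes are
    near-parallel, or the intersection lands implausibly far away, the
    preliminary node is kept.

    Returns the node and, when the intersection was accepted, the fitted
    stem/branch axis directions oriented away from the node.
    """
    n_up = max(2, int(math.ceil(params.refine_slab / params.H)))
    max_jump = 3.0 * params.H + params.eps
    min_span = 0.75 * params.H
    taken0: set = set()
    rows_b = _chain_rows(clusters_per_layer, layer_index, branch_cluster, n_up, max_jump, taken0)
    fit_b = _fit_chain_axis(points, rows_b, min_span)
    if fit_b is None:
        return prelim, None
    cb, ub = fit_b
    best_cand, best_gap, best_axes = None, np.inf, None
    for partner in partner_clusters:
        taken = set(taken0)
        rows_p = _chain_rows(clusters_per_layer, layer_index, partner, n_up, max_jump, taken)
        fit_p = _fit_chain_axis(points, rows_p, min_span)
        if fit_p is None:
            continue
        cp, up = fit_p
        sep = angle_between_deg(ub, up)
        if min(sep, 180.0 - sep) < 8.0:
            continue  # near-parallel axes: intersection ill-conditioned
        cand, gap = _line_closest_point(cb, ub, cp, up)
        if cand is None:
            continue
        dz = cand[2] - prelim[2]
        lateral = float(np.hypot(cand[0] - prelim[0], cand[1] - prelim[1]))
        if not (-2.0 * params.refine_slab <= dz <= params.opt_thickness):
            continue
        if lateral > 2.0 * params.merge_radius:
            continue
        if gap < best_gap:
            best_cand, best_gap = cand, gap
            best_axes = (cp, up, cb, ub)
    if best_cand is None or best_gap > 0.5 * params.merge_radius:
        return prelim, None
    cp, up, cb, ub = best_axes
    # orient each axis away from the node, up its structure
    if np.dot(up, cp - best_cand) < 0:
        up = -up
    if np.dot(ub, cb - best_cand) < 0:
        ub = -ub
    return best_cand, JunctionAxes(up, ub)


# ---------------------------------------------------------------------------
# step 4: branch-point optimization and the angle
# ---------------------------------------------------------------------------

def _alignment_error_deg(group: np.ndarray, center: np.ndarray, node: np.ndarray) -> float:
    """How far a cluster's principal axis points away from the node.

    Clusters at a junction emanate from the node, so the direction from the
    node to the cluster center agrees with the cluster's own axis; clusters
    of unrelated branches crossing the slice do not.
    """
    axis = principal_direction(group)
    radial = center - node
    if np.linalg.norm(radial) == 0:
        return 0.0
    a = angle_between_deg(radial, axis)
    return min(a, 180.0 - a)  # axis sign is arbitrary


def _junction_clusters(
    groups: list[np.ndarray], node: np.ndarray, max_align_deg: float = 30.0
) -> tuple[np.ndarray, np.ndarray]:
    """Pick the stem group and the branch group among slice clusters.

    The stem group is the one whose center is laterally (xy) nearest the
    node.  Among the rest, the branch group is the one whose principal axis
    points back at the node most directly; a candidate whose axis misses
    the node by more than ``max_align_deg`` is rejected (it belongs to some
    other branch crossing the slice, not to this junction).
    """
    centers = [geometric_median(g) for g in groups]
    lateral = [float(np.hypot(c[0] - node[0], c[1] - node[1])) for c in centers]
    stem_i = int(np.argmin(lateral))
    best, best_score = None, np.inf
    for i, (g, c) in enumerate(zip(groups, centers)):
        if i == stem_i:
            continue
        score = _alignment_error_deg(g, c, node)
        if score < best_score:
            best, best_score = i, score
    if best is None or best_score > max_align_deg:
        raise OptimizationError(
            f"no slice cluster points back at the node (best misalignment "
            f"{best_score:.0f} deg)"
        )
    return groups[stem_i], groups[best]


def optimize_branch_points(
    points: np.ndarray,
    node: np.ndarray,
    params: ScagParams,
) -> tuple[np.ndarray, np.ndarray]:
    """Relocate the two branch points a distance ``D`` above the node.

    Points with z in ``[node_z + D, node_z + D + t)`` (t = 1 cm in the cloud
    unit) are clustered with DBSCAN; the robust centers of the stem group
    and the branch group are the optimized branch points.  If the slice does
    not split, the reach is halved and then the depth shrunk by 25% before
    giving up.
    """
    pts = np.asarray(points, dtype=float)
    node = np.asarray(node, dtype=float)
    attempts = (
        (params.eps, params.D),
        (params.eps / 2.0, params.D),
        (params.eps / 2.0, 0.75 * params.D),
    )
    for eps_try, d_try in attempts:
        lo = node[2] + d_try
        hi = lo + params.opt_thickness
        rows = _junction_component_rows(pts, node, eps_try, hi)
        rows = rows[(pts[rows, 2] >= lo) & (pts[rows, 2] < hi)]
        if len(rows) < 2 * params.min_samples:
            continue
        clusters = cluster_layer(pts[rows], eps_try, params.min_samples)
        if len(clusters) < 2:
            continue
        groups = [pts[rows][np.asarray(c.member_indices)] for c in clusters]
        try:
            g_stem, g_branch = _junction_clusters(groups, node)
        except OptimizationError:
            continue
        return geometric_median(g_stem), geometric_median(g_branch)
    raise OptimizationError("optimization slice could not be split into 2 groups")


def _junction_component_rows(
    pts: np.ndarray, node: np.ndarray, eps: float, z_hi: float
) -> np.ndarray:
    """Rows of the band ``[node_z - eps, z_hi)`` connected to the junction.

    Connectivity is eps-chaining (DBSCAN with min_samples=1) over the band.
    A branch crossing the band whose own junction lies below the node is not
    chained to this node's component and is excluded, so it cannot be
    mistaken for this junction's branch.  If no band point sits near the
    node the restriction is skipped.
    """
    band = np.flatnonzero((pts[:, 2] >= node[2] - eps) & (pts[:, 2] < z_hi))
    if len(band) == 0:
        return band
    sub = pts[band]
    labels = DBSCAN(eps=eps, min_samples=1).fit_predict(sub)
    near = np.linalg.norm(sub - node, axis=1) <= 2.0 * eps
    if not np.any(near):
        return band
    vals, counts = np.unique(labels[near], return_counts=True)
    return band[labels == vals[np.argmax(counts)]]


def branch_angle(node, p1, p2) -> float:
    """Angle in degrees at ``node`` between the directions to ``p1`` and ``p2``."""
    node = np.asarray(node, dtype=float)
    a = np.asarray(p1, dtype=float) - node
    b = np.asarray(p2, dtype=float) - node
    return angle_between_deg(a, b)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Candidate:
    layer_index: int
    seeds: tuple
    node: NodeResult
    axes: Optional[JunctionAxes] = None


def detect_nodes(cloud: PointCloud, params: Optional[ScagParams] = None) -> list[_Candidate]:
    """Run stratification, clustering, branch-layer detection and node
    location; return de-duplicated node candidates bottom-to-top.

    Node points closer than ``merge_radius`` are merged, keeping the one
    from the lower layer (several retained layers along one physical branch
    converge to the same junction).
    """
    if params is None:
        params = ScagParams.for_unit(cloud.unit)
    layers = stratify(cloud, params.H)
    clusters_per_layer = [
        cluster_layer(
            cloud.points[ly.member_indices], params.eps, params.min_samples,
            layer_index=ly.index, member_indices=ly.member_indices,
        )
        for ly in layers
    ]
    decisions = detect_branch_layers(
        clusters_per_layer, params.ratio_multiplier, params.min_dist_floor
    )
    candidates: list[_Candidate] = []
    for dec in decisions:
        if not dec.new_branch:
            continue
        upper = clusters_per_layer[dec.upper_layer]
        if len(upper) < 2:
            continue
        a, b = _pair_for_branch(clusters_per_layer[dec.lower_layer], upper)
        seeds = (a.median_point, b.median_point)
        try:
            node = locate_node(cloud.points, seeds, params)
        except GrowthError as exc:
            logger.warning("%s: layer %d: %s", cloud.plant_id, dec.upper_layer, exc)
            continue
        axes = None
        if params.refine:
            partners = [c for c in upper if c is not b]
            refined, axes = refine_node(
                cloud.points, node.node_point, clusters_per_layer,
                b, partners, dec.upper_layer, params,
            )
            node = replace(node, node_point=refined)
        candidates.append(_Candidate(dec.upper_layer, seeds, node, axes))

    kept: list[_Candidate] = []
    for cand in candidates:  # already ordered bottom-to-top
        if all(
            np.linalg.norm(cand.node.node_point - k.node.node_point) >= params.merge_radius
            for k in kept
        ):
            kept.append(cand)
    return kept


def branch_points_for_candidate(
    cloud: PointCloud, cand: _Candidate, params: ScagParams
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Branch points for one located node, with fallbacks.

    Slice optimization is the primary estimator.  When refinement produced
    local axis fits, its angle arbitrates the slice result: a disagreement
    beyond 15 degrees means the slice grabbed the wrong group (typical for
    near-horizontal branches that never reach the slice), and points on the
    fitted axes are used instead.  When optimization fails outright the
    fitted axes, then the pre-optimization seed centers, stand in; both
    fallbacks mark the record degraded.
    """
    node = cand.node.node_point
    reach = params.D + 0.5 * params.opt_thickness
    try:
        p1, p2 = optimize_branch_points(cloud.points, node, params)
        if cand.axes is not None and abs(
            branch_angle(node, p1, p2) - cand.axes.angle_deg
        ) > 15.0:
            p1 = node + reach * cand.axes.stem_dir
            p2 = node + reach * cand.axes.branch_dir
        return p1, p2, False
    except OptimizationError as exc:
        logger.warning("%s: node at z=%.2f: %s", cloud.plant_id, node[2], exc)
        if cand.axes is not None:
            return (
                node + reach * cand.axes.stem_dir,
                node + reach * cand.axes.branch_dir,
                True,
            )
        return cand.seeds[0], cand.seeds[1], True


def run_scag(cloud: PointCloud, params: Optional[ScagParams] = None) -> list[AngleRecord]:
    """Full SCAG pipeline: one :class:`AngleRecord` per detected branch.

    Deterministic for a fixed cloud and parameter set.  Per-branch failures
    (growth or optimization) are logged as warnings; optimization failures
    fall back to the pre-optimization branch points and mark the record
    degraded.
    """
    if params is None:
        params = ScagParams.for_unit(cloud.unit)
    records: list[AngleRecord] = []
    for cand in detect_nodes(cloud, params):
        node = cand.node.node_point
        p1, p2, fell_back = branch_points_for_candidate(cloud, cand, params)
        degraded = cand.node.degraded or fell_back
        try:
            ang = branch_angle(node, p1, p2)
        except ValueError as exc:
            logger.warning("%s: node at z=%.2f: %s", cloud.plant_id, node[2], exc)
            continue
        if not (0.0 < ang < 180.0):
            logger.warning(
                "%s: node at z=%.2f: degenerate angle %.3f dropped", cloud.plant_id, node[2], ang
            )
            continue
        records.append(
            AngleRecord(
                node_point=node, branch_point_1=p1, branch_point_2=p2,
                angle_deg=ang, plant_id=cloud.plant_id, degraded=degraded,
            )
        )
    return records
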