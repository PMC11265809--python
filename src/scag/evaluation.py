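"""Detection metrics, angle agreement and the parameter-sensitivity sweep.

Node matching follows the per-prediction / per-label rule: a predicted node
is a true positive if at least one labelled node lies strictly within the
matching radius (1 cm by convention, about the diameter of a soybean node
region); otherwise it is a false positive.  A labelled node with no
prediction inside its radius is a false negative.  Many-to-one matches are
allowed on both sides.  Recall, precision and F-score follow

    R = TP / (TP + FN),   P = TP / (TP + FP),   F = 2 R P / (R + P),

and angle agreement over matched pairs is summarised by Pearson's r and the
root-mean-square error in degrees.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    ScagParams,
    branch_angle,
    branch_points_for_candidate,
    detect_nodes,
    run_scag,
)
from .io import AngleRecord, PointCloud

logger = logging.getLogger("scag")

__all__ = [
    "MatchResult", "Metrics", "match_nodes", "prf", "angle_agreement",
    "evaluate_plant", "evaluate_suite", "parameter_sweep",
    "DEFAULT_H_GRID", "DEFAULT_N_GRID", "DEFAULT_D_GRID",
]

DEFAULT_H_GRID = (0.5, 1.0, 1.5, 2.0, 2.5, 3.0)
DEFAULT_N_GRID = (20, 30, 40, 60, 80, 100, 120, 140)
DEFAULT_D_GRID = (1.5, 2.0, 2.5, 3.0, 3.5, 4.0)


@dataclass(frozen=True)
class MatchResult:
    TP: int
    FP: int
    FN: int
    matched_pairs: tuple  # (predicted index, label index, distance)


@dataclass(frozen=True)
class Metrics:
    R: float
    P: float
    F: float
    r: float = float("nan")
    RMSE: float = float("nan")


def match_nodes(
    predicted: Sequence, labeled: Sequence, radius: float = 1.0
) -> MatchResult:
    """Match predicted against labelled node points at a strict radius.

    Each matched pair records the nearest label to a true-positive
    prediction; a label may be claimed by several predictions.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pred = np.asarray(predicted, dtype=float).reshape(-1, 3)
    lab = np.asarray(labeled, dtype=float).reshape(-1, 3)
    tp = fp = 0
    pairs = []
    for i, p in enumerate(pred):
        if len(lab) == 0:
            fp += 1
            continue
        d = np.linalg.norm(lab - p, axis=1)
        j = int(np.argmin(d))
        if d[j] < radius:
            tp += 1
            pairs.append((i, j, float(d[j])))
        else:
            fp += 1
    fn = 0
    for l in lab:
        if len(pred) == 0 or float(np.min(np.linalg.norm(pred - l, axis=1))) >= radius:
            fn += 1
    return MatchResult(tp, fp, fn, tuple(pairs))


def prf(TP: int, FP: int, FN: int) -> tuple[float, float, float]:
    """Recall, precision and F-score from match counts.

    An undefined ratio (no labels, or no predictions) is reported as NaN;
    F is 0 when R and P are both 0 and NaN when either is undefined.
    """
    if min(TP, FP, FN) < 0:
        raise ValueError("counts must be non-negative")
    R = TP / (TP + FN) if TP + FN > 0 else float("nan")
    P = TP / (TP + FP) if TP + FP > 0 else float("nan")
    if math.isnan(R) or math.isnan(P):
        F = float("nan")
    elif R + P == 0:
        F = 0.0
    else:
        F = 2.0 * R * P / (R + P)
    return R, P, F


def angle_agreement(pairs: Sequence[tuple[float, float]]) -> tuple[float, float]:
    """Pearson r and RMSE (degrees) over (predicted, reference) angle pairs.

    r needs at least 3 pairs and non-constant margins; RMSE needs one.
    """
    arr = np.asarray(pairs, dtype=float).reshape(-1, 2)
    if len(arr) == 0:
        return float("nan"), float("nan")
    rmse = float(np.sqrt(np.mean((arr[:, 0] - arr[:, 1]) ** 2)))
    if len(arr) < 3 or np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        return float("nan"), rmse
    r = float(np.corrcoef(arr[:, 0], arr[:, 1])[0, 1])
    return r, rmse


# ---------------------------------------------------------------------------
# end-to-end scoring
# ---------------------------------------------------------------------------

def _records_vs_truth(
    records: Sequence[AngleRecord], truth: dict, radius: float
) -> tuple[MatchResult, list[tuple[float, float]]]:
    pred = [r.node_point for r in records]
    match = match_nodes(pred, truth["nodes"], radius)
    pairs = [
        (records[i].angle_deg, truth["angles_deg"][j]) for i, j, _ in match.matched_pairs
    ]
    return match, pairs


def evaluate_plant(
    cloud: PointCloud,
    truth: dict,
    params: Optional[ScagParams] = None,
    radius: float = 1.0,
    records: Optional[Sequence[AngleRecord]] = None,
) -> Metrics:
    """Detect (unless records are given) and score one plant against truth."""
    if records is None:
        records = run_scag(cloud, params)
    match, pairs = _records_vs_truth(records, truth, radius)
    R, P, F = prf(match.TP, match.FP, match.FN)
    r, rmse = angle_agreement(pairs)
    return Metrics(R, P, F, r, rmse)


def evaluate_suite(
    dataset: Sequence[tuple[PointCloud, dict]],
    params: Optional[ScagParams] = None,
    radius: float = 1.0,
    detector=run_scag,
) -> tuple[Metrics, dict]:
    """Pooled metrics over a fixture suite.

    TP/FP/FN are pooled over plants before computing R/P/F; angle pairs are
    pooled before computing r and RMSE.  Also returns the raw pools (counts,
    pairs, absolute errors) for downstream reporting.
    """
    tp = fp = fn = 0
    pairs: list[tuple[float, float]] = []
    for cloud, truth in dataset:
        records = detector(cloud, params)
        match, plant_pairs = _records_vs_truth(records, truth, radius)
        tp += match.TP
        fp += match.FP
        fn += match.FN
        pairs.extend(plant_pairs)
    R, P, F = prf(tp, fp, fn)
    r, rmse = angle_agreement(pairs)
    abs_errors = [abs(a - b) for a, b in pairs]
    pools = {
        "TP": tp, "FP": fp, "FN": fn, "pairs": pairs,
        "mae": float(np.mean(abs_errors)) if abs_errors else float("nan"),
    }
    return Metrics(R, P, F, r, rmse), pools


# ---------------------------------------------------------------------------
# H / N / D grid sweep
# ---------------------------------------------------------------------------

def parameter_sweep(
    dataset: Sequence[tuple[PointCloud, dict]],
    H_grid: Sequence[float] = DEFAULT_H_GRID,
    N_grid: Sequence[int] = DEFAULT_N_GRID,
    D_grid: Sequence[float] = DEFAULT_D_GRID,
    base_params: Optional[ScagParams] = None,
    radius: float = 1.0,
) -> pd.DataFrame:
    """Grid-search sensitivity sweep over slice height, growth number, depth.

    Detection metrics depend only on (H, N), so nodes are located once per
    (H, N) cell and re-used across the D grid, which affects only the angle
    agreement.  Returns the full Cartesian product (duplicates in a grid are
    dropped), sorted by F descending.
    """
    if base_params is None:
        unit = dataset[0][0].unit if dataset else "cm"
        base_params = ScagParams.for_unit(unit)
    H_grid = sorted(dict.fromkeys(H_grid))
    N_grid = sorted(dict.fromkeys(N_grid))
    D_grid = sorted(dict.fromkeys(D_grid))
    if not (H_grid and N_grid and D_grid):
        raise ValueError("grids must be nonempty")

    rows = []
    for H in H_grid:
        for N in N_grid:
            det_params = replace(base_params, H=H, N=int(N))
            per_plant = []  # (cloud, truth, candidates)
            tp = fp = fn = 0
            for cloud, truth in dataset:
                cands = detect_nodes(cloud, det_params)
                match = match_nodes(
                    [c.node.node_point for c in cands], truth["nodes"], radius
                )
                tp += match.TP
                fp += match.FP
                fn += match.FN
                per_plant.append((cloud, truth, cands, match))
            R, P, F = prf(tp, fp, fn)
            for D in D_grid:
                ang_params = replace(det_params, D=D)
                pairs = []
                for cloud, truth, cands, match in per_plant:
                    angles = _candidate_angles(cloud, cands, ang_params)
                    for i, j, _ in match.matched_pairs:
                        if angles[i] is not None:
                            pairs.append((angles[i], truth["angles_deg"][j]))
                r, rmse = angle_agreement(pairs)
                rows.append(
                    {"H": H, "N": int(N), "D": D, "R": R, "P": P, "F": F,
                     "r": r, "RMSE": rmse}
                )
    df = pd.DataFrame(rows)
    return df.sort_values("F", ascending=False, kind="mergesort").reset_index(drop=True)


def _candidate_angles(cloud, candidates, params) -> list:
    """Branch angles for already-located nodes at the given slice depth."""
    out = []
    for cand in candidates:
        p1, p2, _ = branch_points_for_candidate(cloud, cand, params)
        try:
            ang = branch_angle(cand.node.node_point, p1, p2)
        except ValueError:
            out.append(None)
            continue
        out.append(ang if 0.0 < ang < 180.0 else None)
    return out
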