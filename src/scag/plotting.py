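"""Sweep heatmaps and quick-look cloud plots (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["plot_sweep_heatmap", "plot_cloud"]


def plot_sweep_heatmap(sweep: pd.DataFrame, value: str = "F", D: float | None = None):
    """Heatmap of a sweep metric over the (H, N) grid.

    ``value`` is one of the sweep columns (F, R, P, r, RMSE).  Detection
    metrics are D-independent; for r/RMSE pass ``D`` to select a slice
    (defaults to the first D in the table).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = sweep
    if D is not None:
        df = df[np.isclose(df["D"], D)]
    else:
        df = df[np.isclose(df["D"], df["D"].iloc[0])]
    pivot = df.pivot_table(index="N", columns="H", values=value, aggfunc="mean")
    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(pivot.to_numpy(), aspect="auto", origin="lower", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), [f"{h:g}" for h in pivot.columns])
    ax.set_yticks(range(len(pivot.index)), [f"{n:g}" for n in pivot.index])
    ax.set_xlabel("slice height H")
    ax.set_ylabel("growth point number N")
    ax.set_title(value)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    return fig


def plot_cloud(cloud, records=(), elev: float = 10.0, azim: float = -60.0):
    """3D scatter of a plant with detected node/branch points highlighted."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig = plt.figure(figsize=(5, 7))
    ax = fig.add_subplot(projection="3d")
    pts = cloud.points
    step = max(1, len(pts) // 20000)  # cap marker count for speed
    ax.scatter(pts[::step, 0], pts[::step, 1], pts[::step, 2], s=1, c="0.7")
    for r in records:
        tri = np.array([r.branch_point_1, r.node_point, r.branch_point_2])
        ax.plot(tri[:, 0], tri[:, 1], tri[:, 2], "o-", ms=4)
    ax.view_init(elev=elev, azim=azim)
    ax.set_title(cloud.plant_id)
    fig.tight_layout()
    return fig
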