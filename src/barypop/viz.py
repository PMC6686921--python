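"""Diagnostic scatter plots of the GD score space.

Three standard views: GD2 vs GD1 (with the reference triangle), GD3 vs GD1
(the rotated view that separates four-way admixture from two-way
European/Asian admixture), and GD4 vs GD1 (with the quadratic cutoff curves
separating South Asians, Asian-Pacific Islanders and Latin American 2).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .classify import POP_LABELS, CutoffConfig
from .geometry import PlanarFrame

VALID_AXES = (("gd1", "gd2"), ("gd1", "gd3"), ("gd1", "gd4"))

#: Fixed palette keyed by PopID (0 = Unassigned).
POP_COLORS = {
    0: "#999999",
    1: "#1f77b4",
    2: "#8c564b",
    3: "#d62728",
    4: "#9467bd",
    5: "#ff7f0e",
    6: "#e377c2",
    7: "#2ca02c",
    8: "#17becf",
    9: "#bcbd22",
}


def plot_scores(
    scores: pd.DataFrame,
    axes: tuple[str, str] = ("gd1", "gd2"),
    out=None,
    frame: PlanarFrame | None = None,
    cutoffs: CutoffConfig | None = None,
    color_by: str | None = "pop_id",
    max_points: int | None = None,
    seed: int = 0,
):
    """Scatter one of the three GD views; returns the matplotlib figure.

    The reference triangle is drawn on the (gd1, gd2) view when ``frame`` is
    given; both cutoff curves are drawn on the (gd1, gd4) view when
    ``cutoffs`` is given. ``max_points`` subsamples with the given seed (the
    only situation in which subjects are silently not plotted).
    """
    axes = tuple(a.lower() for a in axes)
    if axes not in VALID_AXES:
        raise ValueError(f"axes must be one of {VALID_AXES}, got {axes}")
    if cutoffs is not None and axes == ("gd1", "gd3"):
        raise ValueError("cutoff curves are only defined on the (gd1, gd2)/(gd1, gd4) views")
    if len(scores) == 0:
        raise ValueError("empty scores table")
    for a in axes:
        if a not in scores.columns:
            raise ValueError(f"scores table lacks column {a!r}")

    df = scores
    if max_points is not None and len(df) > max_points:
        df = df.sample(max_points, random_state=seed)

    fig, ax = plt.subplots(figsize=(6, 5))
    xcol, ycol = axes
    if color_by and color_by in df.columns:
        for pid, sub in df.groupby(color_by):
            color = POP_COLORS.get(int(pid) if color_by == "pop_id" else hash(pid) % 10, None)
            label = POP_LABELS.get(pid, str(pid)) if color_by == "pop_id" else str(pid)
            ax.scatter(sub[xcol], sub[ycol], s=6, alpha=0.7, color=color, label=label)
        ax.legend(fontsize=7, markerscale=2, loc="best")
    else:
        ax.scatter(df[xcol], df[ycol], s=6, alpha=0.7, color="#444444")

    if frame is not None and axes == ("gd1", "gd2"):
        tri = np.vstack([frame.vertices2d, frame.vertices2d[0]])
        ax.plot(tri[:, 0], tri[:, 1], color="black", lw=1.0)
        for name, (vx, vy) in zip("EFA", frame.vertices2d):
            ax.annotate(name, (vx, vy), fontsize=9, fontweight="bold")

    if cutoffs is not None and axes == ("gd1", "gd4"):
        gd1 = np.linspace(df[xcol].min(), df[xcol].max(), 300)
        ax.plot(
            gd1,
            cutoffs.sa_coeff * (gd1 - cutoffs.sa_center) ** 2 + cutoffs.sa_offset,
            color="cyan",
            lw=1.0,
        )
        gd4 = np.linspace(df[ycol].min(), df[ycol].max(), 300)
        ax.plot(cutoffs.api_coeff * gd4**2 + cutoffs.api_offset, gd4, color="cyan", lw=1.0)

    ax.set_xlabel(xcol.upper())
    ax.set_ylabel(ycol.upper())
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
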