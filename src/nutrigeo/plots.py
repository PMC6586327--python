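"""Figure rendering: 2-D intake arrays and RMT landscape heat maps."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .geometry2d import IntakeTarget, RailErrorBar, RuleOfCompromiseResult
from .landscape import FmnRegion, LandscapeGrid

__all__ = ["plot_intake_array", "plot_landscape"]


def plot_intake_array(
    result: RuleOfCompromiseResult,
    target: IntakeTarget,
    error_bars: Sequence[RailErrorBar] = (),
    path: str | Path | None = None,
):
    """Intake-array figure: rails, observed per-rail means with rail-aligned
    error bars, the connected array, and the intake target."""
    fig, ax = plt.subplots(figsize=(5, 5))
    pts = np.array(list(result.observed.values()))
    lim = 1.2 * max(pts.max(), target.P_T, target.C_T)
    for rail in result.observed:
        dx, dy = rail.direction
        t = lim / max(dx, dy, 1e-12)
        ax.plot([0, t * dx], [0, t * dy], color="0.2", lw=0.8)
    order = np.argsort(pts[:, 0])
    ax.plot(pts[order, 0], pts[order, 1], "--", color="tab:orange", lw=1.2)
    ax.plot(pts[:, 0], pts[:, 1], "o", color="tab:orange", ms=6, label="observed")
    for bar in error_bars:
        (x0, y0), (x1, y1) = bar.endpoints
        ax.plot([x0, x1], [y0, y1], color="tab:orange", lw=2)
    ax.plot(*target.point, "o", color="tab:blue", ms=9, label="intake target")
    ax.errorbar(
        target.P_T, target.C_T, xerr=target.se[0], yerr=target.se[1],
        color="tab:blue", capsize=3, lw=1,
    )
    ax.set_xlim(0, lim)
    ax.set_ylim(0, lim)
    ax.set_xlabel("protein intake (mg)")
    ax.set_ylabel("carbohydrate intake (mg)")
    ax.set_title(f"intake array — {result.classification}")
    ax.legend(frameon=False)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_landscape(
    grid: LandscapeGrid,
    design_points: np.ndarray | None = None,
    fmn: FmnRegion | None = None,
    title: str = "",
    path: str | Path | None = None,
):
    """Gridded RMT landscape heat map: protein on x, carbohydrate on y,
    lipid along the implicit negative-slope isoclines."""
    fig, ax = plt.subplots(figsize=(5.5, 5))
    im = ax.pcolormesh(grid.P, grid.C, grid.values, cmap="jet", shading="auto")
    fig.colorbar(im, ax=ax, shrink=0.85)
    for iso in range(20, 100, 20):
        ax.plot([0, iso], [iso, 0], color="0.6", lw=0.5)
    if fmn is not None:
        ax.contour(
            grid.P, grid.C, fmn.mask.astype(float), levels=[0.5],
            colors="k", linewidths=1.0,
        )
    if design_points is not None:
        dp = np.asarray(design_points)
        ax.plot(dp[:, 0], dp[:, 1], "ko", ms=4)
    ax.set_xlim(0, 100)
    ax.set_ylim(0, 100)
    ax.set_xlabel("protein (% of macronutrient energy)")
    ax.set_ylabel("carbohydrate (% of macronutrient energy)")
    ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
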