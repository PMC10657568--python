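"""Plotting helpers: ordination scatters and deformation grids."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .tps_warp import DeformationGrid, TpsWarp, warp_points

__all__ = ["plot_scores", "plot_deformation_grid"]


def plot_scores(
    scores: np.ndarray,
    groups: np.ndarray,
    path: str | Path,
    axis_label: str = "PC",
    ellipses: bool = True,
) -> None:
    """Scatter of the first two ordination axes, coloured by group.

    Optionally draws 95% normal-theory ellipses per group (needs >= 3
    members).
    """
    fig, ax = plt.subplots(figsize=(6, 5))
    groups = np.asarray(groups)
    for lv in dict.fromkeys(groups):
        sub = scores[groups == lv]
        pts = ax.scatter(sub[:, 0], sub[:, 1], s=14, label=str(lv), alpha=0.8)
        if ellipses and len(sub) >= 3:
            _ellipse(ax, sub[:, :2], pts.get_facecolor()[0])
    ax.set_xlabel(f"{axis_label}1")
    ax.set_ylabel(f"{axis_label}2")
    ax.legend(fontsize=7, markerscale=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _ellipse(ax, xy: np.ndarray, color) -> None:
    from matplotlib.patches import Ellipse

    mean = xy.mean(axis=0)
    cov = np.cov(xy.T)
    vals, vecs = np.linalg.eigh(cov)
    # 95% coverage of a bivariate normal: chi2(2) quantile 5.991
    width, height = 2 * np.sqrt(np.clip(vals, 0, None) * 5.991)
    angle = np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1]))
    ax.add_patch(
        Ellipse(mean, width=width, height=height, angle=angle,
                facecolor="none", edgecolor=color, lw=1)
    )


def plot_deformation_grid(
    grid: DeformationGrid,
    warp: TpsWarp | None = None,
    path: str | Path = "grid.png",
    n_lines: int = 20,
) -> None:
    """Deformation grid coloured by log2 Jacobian expansion factor.

    Dark cells mark expansion (det J > 1), pale cells contraction, on a
    symmetric colour scale; warped grid lines and the target landmarks are
    overlaid when a warp is given.
    """
    fig, ax = plt.subplots(figsize=(5.5, 5))
    logj = np.log2(np.clip(grid.jacobian, 1e-12, None))
    vmax = max(np.abs(logj).max(), 1e-6)
    ax.pcolormesh(
        grid.x, grid.y, logj, cmap="Greys", vmin=-vmax, vmax=vmax, shading="nearest"
    )
    if warp is not None:
        xs = np.linspace(grid.x[0], grid.x[-1], n_lines)
        ys = np.linspace(grid.y[0], grid.y[-1], n_lines)
        dense = np.linspace(0, 1, 60)
        for xv in xs:
            line = np.column_stack([np.full_like(dense, xv), grid.y[0] + dense * (grid.y[-1] - grid.y[0])])
            w = warp_points(warp, line)
            ax.plot(w[:, 0], w[:, 1], color="steelblue", lw=0.4)
        for yv in ys:
            line = np.column_stack([grid.x[0] + dense * (grid.x[-1] - grid.x[0]), np.full_like(dense, yv)])
            w = warp_points(warp, line)
            ax.plot(w[:, 0], w[:, 1], color="steelblue", lw=0.4)
        ax.scatter(warp.target[:, 0], warp.target[:, 1], s=12, color="crimson", zorder=3)
    ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
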