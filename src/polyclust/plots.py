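"""Thin matplotlib rendering of the plot-ready diagnostic structures.

Everything scientific happens upstream; these functions only draw. A
stable categorical palette maps fine-cluster labels to colors across all
figures (unassigned sets are grey).
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .ensemble_analysis import Ellipsoid

__all__ = [
    "cluster_color",
    "plot_cell_scatter",
    "plot_dendrogram",
    "plot_spread",
    "plot_ellipsoids",
]

_PALETTE = plt.get_cmap("tab10")


def cluster_color(label: int) -> tuple:
    if label < 0:
        return (0.6, 0.6, 0.6, 1.0)
    return _PALETTE(label % 10)


def plot_cell_scatter(df, path: str | Path) -> None:
    """a vs c scatter, one color per fine cluster."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for fine, sub in df.groupby("fine"):
        ax.scatter(sub["a"], sub["c"], s=18, color=cluster_color(int(fine)),
                   label=f"cluster {fine}" if fine >= 0 else "unassigned")
    ax.set_xlabel("a = b (Å)")
    ax.set_ylabel("c (Å)")
    ax.legend(fontsize=7, loc="best")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_dendrogram(export: dict, path: str | Path) -> None:
    """Colored dendrogram from a dendrogram_export structure."""
    fig, ax = plt.subplots(figsize=(max(4, 0.12 * len(export["leaves"])), 4))
    for xs, ys in zip(export["icoord"], export["dcoord"]):
        ax.plot(xs, ys, color="0.3", lw=0.8)
    positions = 5.0 + 10.0 * np.arange(len(export["leaves"]))
    for x, cl in zip(positions, export["leaf_clusters"]):
        ax.plot([x], [0], marker="s", ms=4, color=cluster_color(int(cl)))
    ax.set_xticks([])
    ax.set_ylabel("merge height")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_spread(spread: Mapping[int, float], path: str | Path) -> None:
    """Per-residue largest Cα displacement dot plot."""
    res = sorted(spread)
    fig, ax = plt.subplots(figsize=(6, 3))
    ax.plot(res, [spread[r] for r in res], ".", ms=4, color="0.2")
    ax.set_xlabel("residue")
    ax.set_ylabel("max Cα displacement (Å)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _project_ellipse(e: Ellipsoid, basis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Shadow of a 3D ellipsoid on the plane spanned by ``basis`` (2x3).

    The shadow of {x : xᵀAx ≤ 1} onto a subspace E is the ellipse with
    matrix (E A⁻¹ Eᵀ)⁻¹.
    """
    Ainv = np.linalg.inv(e.shape)
    B = np.linalg.inv(basis @ Ainv @ basis.T)
    center2 = basis @ e.center
    return center2, B


def plot_ellipsoids(
    ellipsoids: Mapping[int | str, Ellipsoid], path: str | Path, residue: int | None = None
) -> None:
    """Per-cluster ellipsoids projected onto the plane of largest spread."""
    centers = np.array([e.center for e in ellipsoids.values()])
    spread_dir = centers - centers.mean(axis=0)
    _, _, Vt = np.linalg.svd(spread_dir if len(centers) > 1 else np.eye(3))
    basis = Vt[:2]
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    theta = np.linspace(0, 2 * np.pi, 200)
    circle = np.stack([np.cos(theta), np.sin(theta)])
    for i, (label, e) in enumerate(ellipsoids.items()):
        c2, B = _project_ellipse(e, basis)
        evals, evecs = np.linalg.eigh(B)
        radii = 1.0 / np.sqrt(np.clip(evals, 1e-300, None))
        pts = (evecs * radii) @ circle + c2[:, None]
        color = cluster_color(label if isinstance(label, int) else i)
        ax.plot(pts[0], pts[1], color=color, label=str(label))
        ax.plot([c2[0]], [c2[1]], "+", color=color)
    ax.set_aspect("equal")
    ax.set_xlabel("principal axis 1 (Å)")
    ax.set_ylabel("principal axis 2 (Å)")
    title = "Cα variation per cluster"
    if residue is not None:
        title += f" at residue {residue}"
    ax.set_title(title, fontsize=9)
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
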