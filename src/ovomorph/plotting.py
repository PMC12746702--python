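"""Plot helpers for embeddings, k-selection diagnostics, enrichment maps and
particles-per-well distribution curves."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402

__all__ = [
    "plot_embedding",
    "plot_k_diagnostics",
    "plot_kde_contours",
    "plot_count_distributions",
]


def plot_embedding(cell_table, color_by: str = "cluster", ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    vals = cell_table[color_by]
    for v in vals.unique():
        sel = vals == v
        ax.scatter(cell_table.loc[sel, "dim1"], cell_table.loc[sel, "dim2"], s=4, label=str(v), alpha=0.6)
    ax.set_xlabel("dim1")
    ax.set_ylabel("dim2")
    ax.legend(markerscale=3, fontsize=8, title=color_by)
    return ax


def plot_k_diagnostics(cluster_model, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ks = sorted(cluster_model.inertia_curve)
    ax.plot(ks, [cluster_model.inertia_curve[k] for k in ks], "o-", label="inertia")
    ax.set_xlabel("k")
    ax.set_ylabel("inertia")
    ax2 = ax.twinx()
    ax2.plot(ks, [cluster_model.silhouette_curve[k] for k in ks], "s--", color="C1", label="silhouette")
    ax2.set_ylabel("mean silhouette")
    ax.axvline(cluster_model.k, color="k", ls=":", lw=1)
    return ax


def plot_kde_contours(maps: dict, extent, ax=None):
    """Overlay per-group density contours on a shared grid."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 5))
    xs, ys = extent
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    for i, (name, dens) in enumerate(maps.items()):
        ax.contour(gx, gy, dens, levels=5, colors=f"C{i}")
        ax.plot([], [], color=f"C{i}", label=name)
    ax.set_xlabel("dim1")
    ax.set_ylabel("dim2")
    ax.legend()
    return ax


def plot_count_distributions(curves, ax=None):
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for col in curves.columns:
        if col == "count":
            continue
        ax.plot(curves["count"], curves[col], label=col)
    ax.set_xlabel("particles per well")
    ax.set_ylabel("smoothed frequency")
    ax.legend()
    return ax
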