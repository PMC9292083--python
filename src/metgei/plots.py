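"""Biplots and diagnostic figures (matplotlib, Agg-safe)."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
from scipy.cluster import hierarchy

from .bilinear import BilinearFit
from .gge import WhichWonWhere, biplot_coords
from .tpe import AccuracyCurve, EnvClustering


def _origin_axes(ax):
    ax.axhline(0, color="grey", lw=0.6)
    ax.axvline(0, color="grey", lw=0.6)


def ammi_biplot(fit: BilinearFit, ax=None, annotate: bool = True):
    """AMMI-2 biplot: symmetric-scaled genotype scores and environment loadings."""
    F, H = biplot_coords(fit, k=2)
    ax = ax or plt.gca()
    _origin_axes(ax)
    ax.scatter(F.iloc[:, 0], F.iloc[:, 1], s=12, color="tab:blue", label="genotypes")
    ax.scatter(H.iloc[:, 0], H.iloc[:, 1], s=20, color="tab:red", marker="^",
               label="environments")
    if annotate:
        for name, (x, y) in F.iterrows():
            ax.annotate(name, (x, y), fontsize=6)
        for name, (x, y) in H.iterrows():
            ax.annotate(name, (x, y), fontsize=6, color="tab:red")
    pct = fit.ss_table["pct_interaction"] if "pct_interaction" in fit.ss_table else None
    ax.set_xlabel("IPC1")
    ax.set_ylabel("IPC2")
    ax.legend(fontsize=7)
    return ax


def gge_polygon_plot(www: WhichWonWhere, ax=None):
    """Which-won-where view: hull polygon plus perpendicular sector rays."""
    ax = ax or plt.gca()
    _origin_axes(ax)
    F, H = www.genotype_coords, www.env_coords
    ax.scatter(F.iloc[:, 0], F.iloc[:, 1], s=12, color="tab:blue")
    ax.scatter(H.iloc[:, 0], H.iloc[:, 1], s=20, color="tab:red", marker="^")
    for name, (x, y) in H.iterrows():
        ax.annotate(name, (x, y), fontsize=6, color="tab:red")
    verts = www.hull_vertices
    pts = F.loc[verts].to_numpy()
    ring = np.vstack([pts, pts[:1]])
    ax.plot(ring[:, 0], ring[:, 1], color="tab:blue", lw=1)
    scale = 1.2 * np.abs(np.vstack([F.to_numpy(), H.to_numpy()])).max()
    for a, b in zip(pts, np.roll(pts, -1, axis=0)):
        edge = b - a
        perp = np.array([-edge[1], edge[0]])
        norm = np.linalg.norm(perp)
        if norm > 0:
            perp = perp / norm * scale
            ax.plot([0, perp[0]], [0, perp[1]], color="grey", lw=0.8, ls="--")
    for name in verts:
        x, y = F.loc[name]
        ax.annotate(name, (x, y), fontsize=7, fontweight="bold")
    ax.set_xlabel("IPC1")
    ax.set_ylabel("IPC2")
    return ax


def accuracy_curve_plot(curve: AccuracyCurve, ax=None):
    ax = ax or plt.gca()
    c = curve.curve
    ax.errorbar(c.index, c["mean_r"], yerr=c["sd_r"], marker="o", capsize=2)
    ax.set_xlabel("number of sampled environments")
    ax.set_ylabel("mean BLUP correlation with full TPE")
    ax.set_ylim(0, 1.05)
    return ax


def dendrogram_plot(clus: EnvClustering, ax=None):
    ax = ax or plt.gca()
    hierarchy.dendrogram(clus.linkage, labels=list(clus.correlation.index), ax=ax,
                         leaf_rotation=90, leaf_font_size=7)
    ax.set_ylabel("Ward linkage height")
    return ax
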