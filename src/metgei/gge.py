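"""GGE (site regression) model and which-won-where sector analysis.

Only the environment main effect is removed before the SVD: the decomposed
matrix z_ij = y_ij - ybar_.j carries genotype main effect and interaction
jointly, so genotype scores describe G + GE.  Biplot coordinates use
symmetric scaling (the singular value split as lambda^0.5 to each side).
The which-won-where analysis takes the convex hull of the genotype markers
in the IPC1-IPC2 plane; each environment belongs to the sector of the hull
vertex whose marker has the largest inner product with the environment
marker — algebraically equivalent to the perpendicular-line construction
drawn on the biplot.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .bilinear import BilinearFit, require_complete, svd_decompose
from .data import TwoWayMeans

logger = logging.getLogger(__name__)


def fit_gge(table: TwoWayMeans, K: int = 2) -> BilinearFit:
    """Fit the GGE model (environment-centered SVD) to a complete table."""
    Y = require_complete(table)
    G, E = Y.shape
    kmax = min(G - 1, E)
    K = min(K, kmax)
    grand = float(Y.mean())
    emain = Y.mean(axis=0) - grand
    Z = Y - Y.mean(axis=0, keepdims=True)
    U, s, V = svd_decompose(Z)
    s = s[:kmax]
    U, V = U[:, :kmax], V[:, :kmax]
    cols = [f"IPC{k + 1}" for k in range(kmax)]
    ss_gge = float((Z**2).sum())
    ss_tot = float(((Y - grand) ** 2).sum())
    ss_env = float(G * (emain**2).sum())
    rows = [
        ("environment", E - 1, ss_env, 100 * ss_env / ss_tot, np.nan),
        ("GGE", (G - 1) * E, ss_gge, 100 * ss_gge / ss_tot, 100.0),
    ]
    for k in range(K):
        ssk = float(s[k] ** 2)
        rows.append(
            (f"IPC{k + 1}", G + E - 1 - 2 * (k + 1), ssk, 100 * ssk / ss_tot,
             100 * ssk / ss_gge if ss_gge > 0 else np.nan)
        )
    ss_res = ss_gge - float((s[:K] ** 2).sum())
    rows.append(("GGE_residual", np.nan, ss_res, 100 * ss_res / ss_tot,
                 100 * ss_res / ss_gge if ss_gge > 0 else np.nan))
    ss_table = pd.DataFrame(
        rows, columns=["source", "df", "SS", "pct_TSS", "pct_GGE"]
    ).set_index("source")
    return BilinearFit(
        model_kind="GGE",
        grand_mean=grand,
        genotype_main=None,
        env_main=pd.Series(emain, index=table.environments),
        singular_values=s,
        genotype_scores=pd.DataFrame(U, index=table.genotypes, columns=cols),
        env_loadings=pd.DataFrame(V, index=table.environments, columns=cols),
        ss_table=ss_table,
        K=K,
        table=table,
    )


def biplot_coords(fit: BilinearFit, k: int = 2) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Symmetric-scaling biplot markers: f_ik = lambda_k^0.5 alpha_ik,
    h_jk = lambda_k^0.5 gamma_jk."""
    return fit.scaled_scores(0.5, k=k), fit.scaled_loadings(0.5, k=k)


@dataclass
class WhichWonWhere:
    hull_vertices: list[str]            # counterclockwise genotype order
    sector_of_env: pd.Series            # environment -> winning vertex genotype
    sectors: dict[str, list[str]]       # winner -> environments
    genotype_coords: pd.DataFrame
    env_coords: pd.DataFrame


def which_won_where(fit: BilinearFit) -> WhichWonWhere:
    """Sector the environments by their winning convex-hull genotype.

    The winner for environment j maximizes f_i . h_j over hull vertices i
    (ties break by genotype identifier).  Degenerate configurations fall
    back gracefully: collinear markers use the two extreme genotypes; all
    markers at the origin give a single trivial sector.
    """
    F, H = biplot_coords(fit, k=2)
    pts = F.to_numpy()
    if np.allclose(pts, 0):
        logger.warning("all genotype markers at the origin; single trivial sector")
        vertices = [sorted(F.index)[0]]
    else:
        try:
            hull = ConvexHull(pts)
            vertices = [F.index[i] for i in hull.vertices]
        except QhullError:
            # collinear: the two extremes along the direction of spread
            d = pts - pts.mean(axis=0)
            axis = d[np.argmax(np.linalg.norm(d, axis=1))]
            proj = d @ axis
            vertices = [F.index[int(np.argmin(proj))], F.index[int(np.argmax(proj))]]
    vert_pts = F.loc[vertices].to_numpy()
    winners = {}
    for env in H.index:
        scores = vert_pts @ H.loc[env].to_numpy()
        best = scores.max()
        cands = sorted(
            v for v, sc in zip(vertices, scores) if np.isclose(sc, best, rtol=0, atol=1e-12)
        )
        winners[env] = cands[0]
    sector_of_env = pd.Series(winners).rename_axis("environment")
    sectors: dict[str, list[str]] = {}
    for env, w in sector_of_env.items():
        sectors.setdefault(w, []).append(env)
    return WhichWonWhere(
        hull_vertices=list(vertices),
        sector_of_env=sector_of_env,
        sectors=sectors,
        genotype_coords=F,
        env_coords=H,
    )
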