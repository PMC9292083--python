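"""AMMI: additive main effects and multiplicative interaction.

The two-way mean table is decomposed as

    y_ij = mu + g_i + e_j + sum_k lambda_k alpha_ik gamma_jk + resid

with main effects from marginal means and the doubly-centered interaction
residual z_ij = y_ij - ybar_i. - ybar_.j + ybar_.. decomposed by SVD.  On top
of the fit sit the AMMI stability value (ASV), the genotype selection index
(GSI = yield rank + ASV rank), AMMI-2 mega-environment delineation (group
environments by their argmax fitted-value genotype), and an EM imputation
scheme for incomplete tables.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bilinear import BilinearFit, require_complete, svd_decompose
from .data import TwoWayMeans
from .errors import FitError, ValidationError

logger = logging.getLogger(__name__)


def fit_ammi(table: TwoWayMeans, K: int | None = None) -> BilinearFit:
    """Fit the AMMI model to a complete two-way table.

    ``K`` is the number of retained multiplicative axes (default: all,
    min(G-1, E-1)).  The SS table reports genotype, environment, interaction
    and per-IPCA sums of squares with shares of total and of interaction SS;
    per-axis df = G + E - 1 - 2k.
    """
    Y = require_complete(table)
    G, E = Y.shape
    kmax = min(G - 1, E - 1)
    K = kmax if K is None else K
    if not (0 <= K <= kmax):
        raise ValidationError(f"K={K} outside [0, {kmax}]")
    grand = float(Y.mean())
    gmain = Y.mean(axis=1) - grand
    emain = Y.mean(axis=0) - grand
    Z = Y - Y.mean(axis=1, keepdims=True) - Y.mean(axis=0, keepdims=True) + grand
    U, s, V = svd_decompose(Z)
    s = s[:kmax]
    U, V = U[:, :kmax], V[:, :kmax]
    cols = [f"IPC{k + 1}" for k in range(kmax)]
    ss_int = float((Z**2).sum())
    ss_tot = float(((Y - grand) ** 2).sum())
    ss_gen = float(E * (gmain**2).sum())
    ss_env = float(G * (emain**2).sum())
    rows = [
        ("genotype", G - 1, ss_gen, 100 * ss_gen / ss_tot, np.nan),
        ("environment", E - 1, ss_env, 100 * ss_env / ss_tot, np.nan),
        ("interaction", (G - 1) * (E - 1), ss_int, 100 * ss_int / ss_tot, 100.0),
    ]
    for k in range(K):
        ssk = float(s[k] ** 2)
        rows.append(
            (f"IPC{k + 1}", G + E - 1 - 2 * (k + 1), ssk,
             100 * ssk / ss_tot, 100 * ssk / ss_int if ss_int > 0 else np.nan)
        )
    ss_resid = ss_int - float((s[:K] ** 2).sum())
    rows.append(
        ("interaction_residual",
         (G - 1) * (E - 1) - sum(G + E - 1 - 2 * (k + 1) for k in range(K)),
         ss_resid, 100 * ss_resid / ss_tot,
         100 * ss_resid / ss_int if ss_int > 0 else np.nan)
    )
    ss_table = pd.DataFrame(
        rows, columns=["source", "df", "SS", "pct_TSS", "pct_interaction"]
    ).set_index("source")
    return BilinearFit(
        model_kind="AMMI",
        grand_mean=grand,
        genotype_main=pd.Series(gmain, index=table.genotypes),
        env_main=pd.Series(emain, index=table.environments),
        singular_values=s,
        genotype_scores=pd.DataFrame(U, index=table.genotypes, columns=cols),
        env_loadings=pd.DataFrame(V, index=table.environments, columns=cols),
        ss_table=ss_table,
        K=K,
        table=table,
    )


def asv(fit: BilinearFit, scaling_exponent: float = 0.5) -> pd.Series:
    """AMMI stability value from the first two axes.

    With scores s_ik = lambda_k^scaling_exponent * alpha_ik and weight
    w = SS_IPCA1/SS_IPCA2 = lambda_1^2/lambda_2^2,

        ASV_i = sqrt((w * s_i1)^2 + s_i2^2).

    The default exponent 0.5 splits the singular value symmetrically (the
    common AMMI-software convention); exponent 0 uses raw alpha scores.
    """
    if len(fit.singular_values) < 2:
        raise ValidationError("ASV needs at least two multiplicative axes")
    l1, l2 = fit.singular_values[0], fit.singular_values[1]
    if l2 <= 1e-10 * max(l1, 1.0):  # numerically zero second axis
        warnings.warn("second singular value is 0; ASV undefined")
        return pd.Series(np.nan, index=fit.genotypes)
    w = (l1 / l2) ** 2
    S = fit.scaled_scores(scaling_exponent, k=2).to_numpy()
    vals = np.sqrt((w * S[:, 0]) ** 2 + S[:, 1] ** 2)
    return pd.Series(vals, index=fit.genotypes, name="ASV")


@dataclass
class StabilityTable:
    table: pd.DataFrame  # mean_yield, ipca1, ipca2, asv, rank_asv, rank_yield, gsi


def _ordinal_rank(values: pd.Series, ascending: bool) -> pd.Series:
    """Competition-free ordinal ranks 1..n; ties broken by identifier."""
    order = values.sort_index().sort_values(ascending=ascending, kind="stable")
    ranks = pd.Series(np.arange(1, len(order) + 1), index=order.index)
    return ranks.reindex(values.index)


def gsi(fit: BilinearFit, asv_values: pd.Series, higher_is_better: bool = True) -> StabilityTable:
    """Genotype selection index: GSI_i = rank(ASV_i) + rank(mean yield_i).

    RY ranks the genotype main effect + grand mean (best = 1 under the trait
    direction); RASV ranks ASV ascending (most stable = 1).  Ranks are
    ordinal with identifier tie-break so GSI stays integral; the table is
    sorted by GSI ascending (then RY, then identifier).
    """
    mean_perf = fit.grand_mean + fit.genotype_main
    ry = _ordinal_rank(mean_perf, ascending=not higher_is_better)
    rasv = _ordinal_rank(asv_values, ascending=True)
    scores = fit.scaled_scores(0.5, k=min(2, fit.K))
    out = pd.DataFrame(
        {
            "mean_yield": mean_perf,
            "ipca1": scores.iloc[:, 0] if fit.K >= 1 else np.nan,
            "ipca2": scores.iloc[:, 1] if fit.K >= 2 else np.nan,
            "asv": asv_values,
            "rank_asv": rasv,
            "rank_yield": ry,
        }
    )
    out["gsi"] = out["rank_asv"] + out["rank_yield"]
    # sort by GSI, ties by yield rank then identifier (index pre-sorted, stable)
    out = out.loc[sorted(out.index)].sort_values(["gsi", "rank_yield"], kind="stable")
    return StabilityTable(out.rename_axis("genotype"))


@dataclass
class MegaEnvAssignment:
    winner_of_env: pd.Series            # environment -> winning genotype
    groups: dict[str, list[str]]        # winner -> environments

    @property
    def n_mega_environments(self) -> int:
        return len(self.groups)


def delineate_mega_envs(fit: BilinearFit, higher_is_better: bool = True) -> MegaEnvAssignment:
    """Group environments by their winning genotype under AMMI-2 fitted values.

    The winner in environment j is the argmax (argmin if lower is better) of
    mu + g_i + e_j + sum_{k<=2} lambda_k alpha_ik gamma_jk over genotypes;
    exact ties break deterministically by genotype identifier.
    """
    if fit.K < 2 and len(fit.singular_values) < 2:
        raise ValidationError("mega-environment delineation needs K >= 2")
    fitted = fit.fitted_values(k=2)
    winners = {}
    for env in fitted.columns:
        col = fitted[env]
        best = col.max() if higher_is_better else col.min()
        cands = sorted(col.index[np.isclose(col, best, rtol=0, atol=1e-12)])
        if len(cands) > 1:
            logger.info("environment %s: tie among %s; taking %s", env, cands, cands[0])
        winners[env] = cands[0]
    winner_of_env = pd.Series(winners).rename_axis("environment")
    groups: dict[str, list[str]] = {}
    for env, w in winner_of_env.items():
        groups.setdefault(w, []).append(env)
    return MegaEnvAssignment(winner_of_env=winner_of_env, groups=groups)


def impute_missing_em(
    table: TwoWayMeans,
    K: int = 2,
    tol: float = 1e-8,
    max_iter: int = 500,
    max_missing_frac: float = 0.2,
) -> TwoWayMeans:
    """EM-AMMI imputation of missing cells.

    Missing cells start at row-mean + column-mean - grand-mean; each sweep
    refits the rank-K AMMI reconstruction and refills the missing cells until
    the largest absolute change drops below ``tol``.
    """
    Y = table.means.copy()
    mask = table.missing_mask
    if not mask.any():
        return table
    frac = mask.mean()
    if frac > max_missing_frac:
        raise ValidationError(
            f"missing fraction {frac:.2f} exceeds ceiling {max_missing_frac}"
        )
    rmean = np.nanmean(Y, axis=1, keepdims=True)
    cmean = np.nanmean(Y, axis=0, keepdims=True)
    grand = np.nanmean(Y)
    fill = (rmean + cmean - grand)
    Y[mask] = np.broadcast_to(fill, Y.shape)[mask]
    for _ in range(max_iter):
        grand = Y.mean()
        g = Y.mean(axis=1, keepdims=True) - grand
        e = Y.mean(axis=0, keepdims=True) - grand
        Z = Y - g - e - grand
        U, s, V = svd_decompose(Z)
        recon = grand + g + e + U[:, :K] @ np.diag(s[:K]) @ V[:, :K].T
        delta = np.max(np.abs(recon[mask] - Y[mask]))
        Y[mask] = recon[mask]
        if delta < tol:
            break
    else:
        raise FitError(f"EM imputation did not converge in {max_iter} sweeps (last delta {delta:.3g})")
    return TwoWayMeans(pd.DataFrame(Y, index=table.genotypes, columns=table.environments))
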