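"""Cultivar superiority index and the cross-model stability report.

The Lin-Binns superiority index of genotype i over n environments is

    P_i = sum_j (X_ij - M_j)^2 / (2n),

with M_j the best value in environment j under the trait's direction of
merit.  It decomposes exactly into a genetic distance term and a GEI term:

    P_i = [ n (Xbar_i. - Mbar)^2 + sum_j (X_ij - M_j - Xbar_i. + Mbar)^2 ] / (2n).

Small P_i means consistently near the per-environment best.  The stability
report merges the Finlay-Wilkinson, AMMI and superiority views per genotype
and appends Spearman correlations among the measures.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .ammi import StabilityTable
from .data import TwoWayMeans
from .fw import FwFit

logger = logging.getLogger(__name__)


@dataclass
class SuperiorityTable:
    table: pd.DataFrame  # mean_perf, p_i, genetic_term, gei_term, rank
    n_env: int


def superiority_index(table: TwoWayMeans, higher_is_better: bool = True) -> SuperiorityTable:
    """Lin-Binns P_i with its genetic/GEI decomposition, ranked ascending.

    Missing cells restrict each genotype to its observed environments (with
    a log note); a single environment makes P_i uninformative and is flagged.
    """
    T = table.table
    n_env = T.shape[1]
    if n_env < 2:
        logger.warning("superiority index over a single environment is uninformative")
    if not table.is_complete:
        logger.info("incomplete table: P_i computed over each genotype's observed environments")
    M = T.max(axis=0) if higher_is_better else T.min(axis=0)
    rows = {}
    for g in T.index:
        y = T.loc[g].dropna()
        m = M[y.index]
        n = len(y)
        if n == 0:
            rows[g] = dict(mean_perf=np.nan, p_i=np.nan, genetic_term=np.nan, gei_term=np.nan)
            continue
        d = (y - m).to_numpy()
        p_i = float((d**2).sum() / (2 * n))
        xbar, mbar = float(y.mean()), float(m.mean())
        genetic = float(n * (xbar - mbar) ** 2 / (2 * n))
        gei = float(((d - (xbar - mbar)) ** 2).sum() / (2 * n))
        rows[g] = dict(mean_perf=xbar, p_i=p_i, genetic_term=genetic, gei_term=gei)
    out = pd.DataFrame(rows).T.rename_axis("genotype")
    out["rank"] = out["p_i"].rank(method="first").astype("Int64")
    return SuperiorityTable(out.sort_values("p_i"), n_env=n_env)


def stability_report(
    fw: FwFit | None = None,
    ammi_stab: StabilityTable | None = None,
    sup: SuperiorityTable | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge the per-genotype stability measures into one table.

    Returns ``(report, spearman)``: the merged per-genotype table (union of
    genotypes; missing fields stay NaN) and the Spearman correlation matrix
    among the numeric stability measures.
    """
    pieces = []
    if fw is not None:
        pieces.append(
            fw.genotype_rows[["slope", "mse", "rank_slope"]].rename(
                columns={"slope": "fw_slope", "mse": "fw_mse", "rank_slope": "fw_rank"}
            )
        )
    if ammi_stab is not None:
        pieces.append(
            ammi_stab.table[["mean_yield", "asv", "rank_asv", "rank_yield", "gsi"]]
        )
    if sup is not None:
        pieces.append(sup.table[["p_i", "rank"]].rename(columns={"rank": "rank_p_i"}))
    if not pieces:
        raise ValueError("at least one stability input required")
    report = pd.concat(pieces, axis=1, join="outer").rename_axis("genotype").sort_index()
    measures = [c for c in ("fw_slope", "fw_mse", "asv", "p_i", "gsi") if c in report]
    sub = report[measures].dropna()
    if len(sub) >= 3 and len(measures) >= 2:
        rho, _ = stats.spearmanr(sub.to_numpy())
        rho = np.atleast_2d(rho)
        spearman = pd.DataFrame(rho, index=measures, columns=measures)
    else:
        spearman = pd.DataFrame(index=measures, columns=measures, dtype=float)
    return report, spearman
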