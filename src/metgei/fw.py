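"""Finlay-Wilkinson joint regression on standardized two-way means.

Each trait's genotype x environment mean table is first standardized to
overall mean 0 and SD 1 (denominator n-1, over non-missing cells), so slope
and MSE summaries are comparable across traits measured in different units.
The environmental index e_j is the mean over genotypes of the standardized
means in environment j; each genotype's standardized means are then
regressed on e_j by ordinary least squares, giving an intercept g_i (general
performance), a sensitivity slope beta_i (average sensitivity = 1), and a
residual MSE (deviation-from-regression stability).

Two stability orderings are emitted: by raw slope ascending (smallest
sensitivity first, the presentation used for cassava yield trials) and by
|beta - 1| (distance from average sensitivity, the textbook convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data import TwoWayMeans
from .errors import ValidationError

logger = logging.getLogger(__name__)


def standardize(table: TwoWayMeans) -> TwoWayMeans:
    """Scale to overall mean 0, SD 1 (ddof=1) over non-missing cells."""
    vals = table.means
    obs = vals[~np.isnan(vals)]
    if obs.size < 2:
        raise ValidationError("need >=2 non-missing cells to standardize")
    sd = float(np.std(obs, ddof=1))
    if sd == 0:
        raise ValidationError("zero standard deviation; cannot standardize")
    out = (table.table - float(obs.mean())) / sd
    return TwoWayMeans(out)


@dataclass
class FwFit:
    env_index: pd.Series                 # e_j on the standardized scale
    genotype_rows: pd.DataFrame          # intercept, slope, mse, n_env, ranks
    trait_summaries: dict[str, float]
    table: TwoWayMeans                   # the standardized table used


def fit_fw(table: TwoWayMeans, standardized: bool = False, min_envs: int = 3) -> FwFit:
    """Fit the joint regression.  ``table`` is standardized first unless the
    caller says it already is.  Genotypes observed in fewer than ``min_envs``
    environments are excluded with a warning."""
    std = table if standardized else standardize(table)
    T = std.table
    env_index = T.mean(axis=0, skipna=True)
    rows = {}
    for g in T.index:
        y = T.loc[g]
        ok = y.notna() & env_index.notna()
        n = int(ok.sum())
        if n < min_envs:
            logger.warning("genotype %s observed in %d < %d environments; excluded", g, n, min_envs)
            continue
        x = env_index[ok].to_numpy()
        yy = y[ok].to_numpy()
        res = stats.linregress(x, yy)
        resid = yy - (res.intercept + res.slope * x)
        mse = float(resid @ resid / (n - 2)) if n > 2 else float("nan")
        rows[g] = {"intercept": res.intercept, "slope": res.slope, "mse": mse, "n_env": n}
    if not rows:
        raise ValidationError("no genotype with enough environments")
    gr = pd.DataFrame(rows).T.rename_axis("genotype")
    gr["n_env"] = gr["n_env"].astype(int)
    # ranks: raw low slope first (field presentation), and |slope-1| (textbook)
    gr["rank_slope"] = gr["slope"].rank(method="first").astype(int)
    gr["rank_abs_dev"] = (gr["slope"] - 1.0).abs().rank(method="first").astype(int)
    summaries = {
        "slope_median": float(gr["slope"].median()),
        "slope_variance": float(gr["slope"].var(ddof=1)),
        "mse_median": float(gr["mse"].median()),
        "mse_variance": float(gr["mse"].var(ddof=1)),
    }
    return FwFit(env_index=env_index, genotype_rows=gr, trait_summaries=summaries, table=std)


def fw_anova(fit: FwFit) -> pd.DataFrame:
    """ANOVA of the joint regression on a complete standardized table.

    Strata: genotypes, environments (the common regression on the index),
    heterogeneity of slopes, and residual; the slope-heterogeneity F-test is
    against the residual stratum.  With only two environments the fit is
    saturated and heterogeneity is untestable (reported missing).
    """
    T = fit.table.table
    if T.isna().any().any():
        raise ValidationError("fw_anova requires a complete table")
    G, E = T.shape
    vals = T.to_numpy()
    grand = vals.mean()
    gmeans = vals.mean(axis=1)
    e = fit.env_index.to_numpy()
    ss_total = float(((vals - grand) ** 2).sum())
    ss_gen = float(E * ((gmeans - grand) ** 2).sum())
    ss_env = float(G * ((e - e.mean()) ** 2).sum())
    sxx = float(((e - e.mean()) ** 2).sum())
    slopes = fit.genotype_rows["slope"].reindex(T.index).to_numpy()
    ss_het = float(((slopes - 1.0) ** 2).sum() * sxx)
    ss_res = ss_total - ss_gen - ss_env - ss_het
    df_gen, df_env, df_het = G - 1, E - 1, G - 1
    df_res = (G - 1) * (E - 2)
    rows = [
        ("genotype", df_gen, ss_gen),
        ("environment", df_env, ss_env),
        ("sensitivity", df_het, ss_het),
        ("residual", df_res, ss_res),
        ("total", G * E - 1, ss_total),
    ]
    out = pd.DataFrame(rows, columns=["source", "df", "SS"]).set_index("source")
    out["MS"] = out["SS"] / out["df"].replace(0, np.nan)
    if df_res > 0:
        ms_res = out.loc["residual", "MS"]
        f = out.loc["sensitivity", "MS"] / ms_res
        out.loc["sensitivity", "F"] = f
        out.loc["sensitivity", "p_value"] = float(stats.f.sf(f, df_het, df_res))
        fe = out.loc["environment", "MS"] / ms_res
        out.loc["environment", "F"] = fe
        out.loc["environment", "p_value"] = float(stats.f.sf(fe, df_env, df_res))
        fg = out.loc["genotype", "MS"] / ms_res
        out.loc["genotype", "F"] = fg
        out.loc["genotype", "p_value"] = float(stats.f.sf(fg, df_gen, df_res))
    else:
        out["F"] = np.nan
        out["p_value"] = np.nan
    return out
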