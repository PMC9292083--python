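"""Combined multi-environment mixed model and its derived statistics.

The joint model for one trait is

    y_ijk = mu + g_i + e_j + b_k(j) + ge_ij + beta*p + eps_ijk

with genotype, environment, block-within-environment and genotype-by-
environment all random, fit by REML.  From it come:

* the percent-of-phenotypic-variance table over the random terms + residual,
* across-environment heritability on a plot-mean basis,
  H2 = var_g / (var_g + var_ge/e + var_eps/(e*r)), with r the harmonic mean
  of trial replicate counts,
* likelihood-ratio tests for the presence of GEI (boundary-corrected 50:50
  {0, chi2_1} mixture null) and for heterogeneity of the residual variance
  across trials (chi2 with n_env - 1 df),
* the partition of GEI into a repeatable genotype-by-location part and
  non-repeatable genotype-by-year and genotype-by-location-by-year parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data import MetDataset
from .errors import FitError, ValidationError
from .mixed import Factor, MixedFit, MixedModel, design_fixed

logger = logging.getLogger(__name__)

JOINT_TERMS = ("genotype", "environment", "block_within_env", "gei")


@dataclass
class VarianceComponents:
    """Named variance components with percent-of-phenotypic shares."""

    components: dict[str, float]     # random terms + "residual"
    percents: dict[str, float]       # same keys, sums to 100
    loglik: float
    fit: MixedFit = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variance": self.components, "percent": self.percents}
        ).rename_axis("component")


@dataclass
class LrtResult:
    statistic: float
    df: str
    p_value: float
    full_better: bool
    loglik_full: float
    loglik_reduced: float


@dataclass
class GeiPartition:
    components: dict[str, float]
    percents: dict[str, float]
    p_values: dict[str, float]       # per-term boundary LRT
    loglik: float
    fit: MixedFit = field(repr=False, default=None)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"variance": self.components, "percent": self.percents,
             "p_value": pd.Series(self.p_values)}
        ).rename_axis("component")


def _joint_model(
    data: MetDataset,
    trait: str,
    heterogeneous_error: bool,
    drop_terms: tuple[str, ...] = (),
) -> tuple[MixedModel, pd.DataFrame]:
    sub = data.df.dropna(subset=[trait]).reset_index(drop=True)
    if sub["environment"].nunique() < 2:
        raise ValidationError("joint analysis needs >=2 environments")
    use_cov = data.trait_registry[trait].uses_covariate
    X = design_fixed(sub, "prop_harvested" if use_cov else None, rep_fixed=False)
    env = Factor.from_series(sub["environment"])
    gt = Factor.from_series(sub["genotype"])
    terms = {
        "genotype": gt,
        "environment": env,
        "block_within_env": Factor.from_series(
            sub["environment"].astype(str) + "/" + sub["replicate"].astype(str)
        ),
        "gei": Factor.cross(gt, env),
    }
    for t in drop_terms:
        terms.pop(t)
    model = MixedModel(
        sub[trait].to_numpy(float), X, terms,
        resid_factor=env if heterogeneous_error else None,
    )
    return model, sub


def _percents(components: dict[str, float]) -> dict[str, float]:
    total = sum(components.values())
    return {k: 100.0 * v / total for k, v in components.items()}


def fit_joint(
    data: MetDataset,
    trait: str,
    heterogeneous_error: bool = False,
    pev_terms: tuple[str, ...] = ("genotype",),
    start: dict | None = None,
    resid_start: float | None = None,
) -> VarianceComponents:
    """REML fit of the joint model; genotype and GEI BLUPs retrievable
    from ``.fit``.  With ``heterogeneous_error`` one residual variance is
    estimated per environment and the percent table uses their plot-weighted
    mean."""
    model, sub = _joint_model(data, trait, heterogeneous_error)
    fit = model.fit(pev_terms=pev_terms, start=start, resid_start=resid_start)
    comps = dict(fit.var_components)
    if heterogeneous_error:
        counts = sub.groupby("environment").size().reindex(fit.resid_var.index)
        comps["residual"] = fit.mean_resid_var(weights=counts.to_numpy())
    else:
        comps["residual"] = fit.resid_var
    return VarianceComponents(
        components=comps, percents=_percents(comps), loglik=fit.loglik, fit=fit
    )


def harmonic_mean_reps(reps: list[int]) -> float:
    """Effective replicate count: harmonic mean n / sum(1/r_i)."""
    if not reps:
        raise ValueError("empty replicate list")
    reps = np.asarray(reps, float)
    if (reps < 1).any():
        raise ValueError("replicate counts must be >= 1")
    return float(len(reps) / np.sum(1.0 / reps))


def h2_across(vc: VarianceComponents, n_env: int, n_reps_effective: float) -> float:
    """Across-environment plot-mean heritability
    sigma2_g / (sigma2_g + sigma2_ge/e + sigma2_eps/(e*r))."""
    if n_env < 1 or n_reps_effective <= 0:
        raise ValueError("n_env >= 1 and n_reps_effective > 0 required")
    g = vc.components["genotype"]
    ge = vc.components.get("gei", 0.0)
    eps = vc.components["residual"]
    denom = g + ge / n_env + eps / (n_env * n_reps_effective)
    if denom == 0:
        return float("nan")
    return g / denom


def _boundary_p(stat: float) -> float:
    """p-value under the 50:50 mixture of a point mass at 0 and chi2_1."""
    if stat <= 1e-12:
        return 1.0
    return 0.5 * float(stats.chi2.sf(stat, 1))


def _lrt(full_ll: float, red_ll: float, p_fun, df: str) -> LrtResult:
    stat = 2.0 * (full_ll - red_ll)
    # a nested fit at the boundary can sit ~1e-4 below its reduced model from
    # the D vs G^-1 cancellation in log|C|; clamp tiny deficits to 0
    if stat < -1e-2:
        raise FitError(
            f"reduced model log-likelihood exceeds full model ({stat:.3g}); "
            "refit with different starts"
        )
    stat = max(stat, 0.0)
    return LrtResult(
        statistic=stat, df=df, p_value=p_fun(stat),
        full_better=stat > 0, loglik_full=full_ll, loglik_reduced=red_ll,
    )


def lrt_gei(data: MetDataset, trait: str, mixture_null: bool = True) -> LrtResult:
    """Test presence of GEI: joint model with vs without the ge term.

    The GEI variance sits on the boundary of its parameter space under the
    null, so the default null is the equal mixture {0, chi2_1}; a plain
    chi2_1 is available as a conservative option.
    """
    model_full, sub = _joint_model(data, trait, False)
    full = model_full.fit()
    model_red, _ = _joint_model(data, trait, False, drop_terms=("gei",))
    red = model_red.fit()
    if full.loglik < red.loglik - 1e-9:
        # near-boundary flat likelihood: restart the full fit from the
        # reduced solution with a tiny interaction variance
        start = dict(red.var_components)
        start["gei"] = 1e-4 * float(np.var(sub[trait]))
        refit = model_full.fit(start=start, resid_start=red.resid_var)
        if refit.loglik > full.loglik:
            full = refit
    p_fun = _boundary_p if mixture_null else (lambda s: float(stats.chi2.sf(s, 1)) if s > 0 else 1.0)
    return _lrt(full.loglik, red.loglik, p_fun, "0.5*chi2_0 + 0.5*chi2_1" if mixture_null else "chi2_1")


def lrt_error_heterogeneity(data: MetDataset, trait: str) -> LrtResult:
    """Test per-environment vs pooled residual variances (df = n_env - 1)."""
    pooled = fit_joint(data, trait, heterogeneous_error=False, pev_terms=())
    # warm start at the pooled solution: the heterogeneous fit can then only
    # improve, so the LRT statistic is nonnegative by construction
    het = fit_joint(
        data, trait, heterogeneous_error=True, pev_terms=(),
        start=dict(pooled.fit.var_components), resid_start=float(pooled.fit.resid_var),
    )
    n_env = data.df["environment"].nunique()
    df = n_env - 1
    return _lrt(
        het.loglik, pooled.loglik,
        lambda s: float(stats.chi2.sf(s, df)) if s > 0 else 1.0, f"chi2_{df}",
    )


PARTITION_TERMS = (
    "genotype", "location", "year", "location:year", "block_within_env",
    "genotype:location", "genotype:year", "genotype:location:year",
)


def partition_gei(
    data: MetDataset, trait: str, lrt_terms: tuple[str, ...] = (
        "genotype:location", "genotype:year", "genotype:location:year"
    )
) -> GeiPartition:
    """Partition GEI into GL (repeatable), GY and GLY (non-repeatable).

    Fits random genotype, location, year, location x year, block, G x L,
    G x Y, G x L x Y and residual, and attaches a boundary LRT p-value to
    each interaction term.  With a single year the year-involving terms are
    inestimable and reported missing.
    """
    sub = data.df.dropna(subset=[trait]).reset_index(drop=True)
    n_loc = sub["location"].nunique()
    n_year = sub["year"].nunique()
    if n_loc < 2:
        raise ValidationError("partition needs >=2 locations")
    single_year = n_year < 2
    loc_years = sub.groupby("location")["year"].nunique()
    if (loc_years == 1).any() and not single_year:
        logger.warning(
            "location(s) %s observed in a single year; G x L x Y partially confounded",
            list(loc_years.index[loc_years == 1]),
        )
    use_cov = data.trait_registry[trait].uses_covariate
    X = design_fixed(sub, "prop_harvested" if use_cov else None, rep_fixed=False)
    gt = Factor.from_series(sub["genotype"])
    loc = Factor.from_series(sub["location"])
    yr = Factor.from_series(sub["year"].astype(str))
    ly = Factor.cross(loc, yr)
    terms = {
        "genotype": gt,
        "location": loc,
        "location:year": ly,
        "block_within_env": Factor.from_series(
            sub["environment"].astype(str) + "/" + sub["replicate"].astype(str)
        ),
        "genotype:location": Factor.cross(gt, loc),
    }
    if not single_year:
        terms["year"] = yr
        terms["genotype:year"] = Factor.cross(gt, yr)
        terms["genotype:location:year"] = Factor.cross(gt, ly)
    y = sub[trait].to_numpy(float)

    def _fit(drop: str | None = None, start=None):
        t = {k: v for k, v in terms.items() if k != drop}
        return MixedModel(y, X, t).fit(start=start)

    full = _fit()
    comps = dict(full.var_components)
    comps["residual"] = full.resid_var
    if single_year:
        comps["year"] = float("nan")
        comps["genotype:year"] = float("nan")
        comps["genotype:location:year"] = float("nan")
    known = {k: v for k, v in comps.items() if np.isfinite(v)}
    percents = _percents(known)
    percents.update({k: float("nan") for k in comps if k not in known})
    p_values = {}
    for term in lrt_terms:
        if term not in full.var_components:
            p_values[term] = float("nan")
            continue
        red = _fit(drop=term, start=full.var_components)
        stat = max(0.0, 2.0 * (full.loglik - red.loglik))
        p_values[term] = _boundary_p(stat)
    return GeiPartition(
        components=comps, percents=percents, p_values=p_values,
        loglik=full.loglik, fit=full,
    )
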