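"""Per-trial mixed-model analysis and quality-control filtering.

Each trial is fit as  y = mu + replicate (fixed) + beta*p + genotype (random)
+ error  by REML.  Trial quality is judged on three statistics:

* ``CV% = 100 * sigma_e / ybar`` — residual coefficient of variation,
* ``H2 = var_g / (var_g + var_e)`` — plot-basis broad-sense heritability,
* ``Ac = sqrt(1 - PEV / var_g)`` — accuracy of genotype BLUPs, with PEV the
  genotype-wise average prediction error variance.

The default removal thresholds are H2 < 0.1, Ac < 0.4 or CV > 40.5, with
strict inequalities (a trial exactly at a threshold is kept).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import MetDataset
from .errors import ValidationError
from .mixed import Factor, MixedModel, design_fixed

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = {"h2_min": 0.1, "ac_min": 0.4, "cv_max": 40.5}


@dataclass
class TrialSummary:
    """QC statistics of one trial for one trait."""

    trial: str
    environment: str
    trait: str
    n_reps: int
    n_genotypes: int
    trait_mean: float
    var_g: float
    var_e: float
    mean_pev: float
    cv_pct: float
    h2_plot: float
    accuracy: float
    var_g_boundary: bool = False
    passed_qc: bool | None = None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


def fit_single_trial(data: MetDataset, trial: str, trait: str) -> TrialSummary:
    """REML fit of one trial; returns its QC summary.

    A genotypic variance estimated at the zero boundary yields accuracy 0
    (flagged), not an exception.
    """
    sub = data.df[data.df["trial"] == trial].dropna(subset=[trait])
    if sub.empty:
        raise ValidationError(f"trial '{trial}' has no data for '{trait}'")
    if sub["replicate"].nunique() < 2 or sub["genotype"].nunique() < 2:
        raise ValidationError(f"trial '{trial}' needs >=2 replicates and >=2 genotypes")
    use_cov = data.trait_registry[trait].uses_covariate
    X = design_fixed(sub, "prop_harvested" if use_cov else None, rep_fixed=True)
    gfac = Factor.from_series(sub["genotype"])
    model = MixedModel(sub[trait].to_numpy(float), X, {"genotype": gfac})
    fit = model.fit(pev_terms=("genotype",))
    var_g = fit.var_components["genotype"]
    var_e = fit.mean_resid_var()
    pev = fit.pev("genotype")
    mean_pev = float(np.mean(np.diag(pev)))
    ybar = float(sub[trait].mean())
    cv = 100.0 * np.sqrt(var_e) / ybar
    h2 = var_g / (var_g + var_e) if (var_g + var_e) > 0 else np.nan
    # a genotypic variance ~1000x below the error variance is a boundary
    # estimate for QC purposes: the accuracy formula is meaningless there
    at_boundary = fit.boundary["genotype"] or var_g <= 1e-3 * var_e
    acc = 0.0 if at_boundary else float(np.sqrt(max(0.0, 1.0 - mean_pev / var_g)))
    if at_boundary:
        logger.warning("trial %s: genotypic variance at boundary; accuracy set to 0", trial)
    return TrialSummary(
        trial=trial,
        environment=sub["environment"].iloc[0],
        trait=trait,
        n_reps=int(sub["replicate"].nunique()),
        n_genotypes=int(sub["genotype"].nunique()),
        trait_mean=ybar,
        var_g=var_g,
        var_e=var_e,
        mean_pev=mean_pev,
        cv_pct=float(cv),
        h2_plot=float(h2),
        accuracy=acc,
        var_g_boundary=at_boundary,
    )


def fit_all_trials(data: MetDataset, trait: str) -> list[TrialSummary]:
    out = []
    for trial in data.trials:
        try:
            out.append(fit_single_trial(data, trial, trait))
        except ValidationError as exc:
            logger.warning("skipping trial %s: %s", trial, exc)
    return out


def qc_filter(
    summaries: list[TrialSummary],
    thresholds: dict | None = None,
) -> tuple[list[TrialSummary], list[TrialSummary]]:
    """Partition trials into (kept, removed) under the QC thresholds.

    A trial is removed iff H2 < h2_min OR Ac < ac_min OR CV > cv_max
    (strict inequalities: values exactly at a threshold are kept).
    Order is preserved and ``passed_qc`` is set on every summary.
    """
    th = {**DEFAULT_THRESHOLDS, **(thresholds or {})}
    kept, removed = [], []
    for s in summaries:
        fails = (
            s.h2_plot < th["h2_min"]
            or s.accuracy < th["ac_min"]
            or s.cv_pct > th["cv_max"]
        )
        s.passed_qc = not fails
        (removed if fails else kept).append(s)
    return kept, removed


def summaries_frame(summaries: list[TrialSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.as_dict() for s in summaries])
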