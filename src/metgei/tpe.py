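"""Representativeness of the target population of environments (TPE).

Treating all tested environments as the TPE, each environment is scored by

* the Pearson correlation r between its environment-specific genotypic BLUPs
  (genotype random within that environment) and the genotypic BLUPs from the
  joint across-environment model, and
* its Cullis heritability H2 = 1 - vbar_Delta / (2 sigma2_g), where
  vbar_Delta is the mean prediction error variance of a difference of two
  genotypic BLUPs,

then ranked by the sum of the two ranks (high r and high H2 -> small rank).
An accuracy curve resamples environment subsets of size 1..E-1 (50 draws by
default), refits the joint model on each subset, and averages the
correlation of subset BLUPs with all-environment BLUPs.  Finally,
environments are clustered from the G x E interaction BLUPs: Pearson
correlation between environment columns, distance sqrt(2(1-r)) (Euclidean-
compatible, as Ward's objective requires), Ward linkage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .data import MetDataset
from .errors import FitError, ValidationError
from .joint import fit_joint
from .mixed import Factor, MixedFit, MixedModel, design_fixed, mean_pairwise_pev_difference

logger = logging.getLogger(__name__)


def cullis_h2(vbar_delta: float, var_g: float) -> tuple[float, bool]:
    """Cullis heritability 1 - vbar_Delta/(2 sigma2_g), clipped to [0, 1].

    Returns ``(h2, clipped_or_boundary_flag)``; a zero genotypic variance
    yields (0.0, True).
    """
    if var_g <= 0:
        return 0.0, True
    h2 = 1.0 - vbar_delta / (2.0 * var_g)
    clipped = h2 < 0 or h2 > 1
    return float(min(1.0, max(0.0, h2))), clipped


def fit_env_genotype_model(data: MetDataset, env: str, trait: str) -> MixedFit:
    """Genotype-random model within one environment (replicate fixed,
    harvested-proportion covariate when the trait uses it)."""
    sub = data.df[(data.df["environment"] == env)].dropna(subset=[trait])
    if sub["genotype"].nunique() < 3:
        raise ValidationError(f"environment {env} has <3 genotypes")
    use_cov = data.trait_registry[trait].uses_covariate
    X = design_fixed(sub, "prop_harvested" if use_cov else None, rep_fixed=True)
    model = MixedModel(
        sub[trait].to_numpy(float), X, {"genotype": Factor.from_series(sub["genotype"])}
    )
    return model.fit(pev_terms=("genotype",))


def env_cullis_h2(fit: MixedFit) -> tuple[float, bool]:
    var_g = fit.var_components["genotype"]
    if var_g <= 0 or fit.boundary["genotype"]:
        return 0.0, True
    vbar = mean_pairwise_pev_difference(fit.pev("genotype"))
    return cullis_h2(vbar, var_g)


def _ordinal_rank_desc(values: pd.Series) -> pd.Series:
    order = values.loc[sorted(values.index)].sort_values(ascending=False, kind="stable")
    return pd.Series(np.arange(1, len(order) + 1), index=order.index).reindex(values.index)


def rank_environments(data: MetDataset, trait: str) -> pd.DataFrame:
    """Per-environment r (BLUP correlation with the TPE) and Cullis H2,
    ranked by the sum of the two ranks (ascending)."""
    joint = fit_joint(data, trait, pev_terms=())
    overall = joint.fit.blups["genotype"]
    rows = {}
    for env in data.environments:
        try:
            fit = fit_env_genotype_model(data, env, trait)
        except (ValidationError, FitError) as exc:
            logger.warning("environment %s excluded: %s", env, exc)
            continue
        blups = fit.blups["genotype"]
        shared = blups.index.intersection(overall.index)
        r = float(np.corrcoef(blups[shared], overall[shared])[0, 1])
        h2, flagged = env_cullis_h2(fit)
        rows[env] = {"r": r, "h2_cullis": h2, "h2_flagged": flagged}
    out = pd.DataFrame(rows).T.rename_axis("environment")
    out["rank_r"] = _ordinal_rank_desc(out["r"]).astype(int)
    out["rank_h2"] = _ordinal_rank_desc(out["h2_cullis"]).astype(int)
    out["sum_ranks"] = out["rank_r"] + out["rank_h2"]
    return out.sort_values(["sum_ranks", "rank_r"], kind="stable")


@dataclass
class AccuracyCurve:
    curve: pd.DataFrame      # subset_size, mean_r, sd_r, n_ok, n_skipped
    n_samples: int
    seed: int

    def finite_differences(self) -> pd.Series:
        return self.curve["mean_r"].diff()


def accuracy_curve(
    data: MetDataset,
    trait: str,
    n_samples: int = 50,
    seed: int = 0,
    include_full: bool = True,
) -> AccuracyCurve:
    """Mean BLUP correlation against number of sampled environments.

    For each subset size s in 1..E-1, ``n_samples`` uniform environment
    subsets are drawn without replacement; the joint model is refit on each
    (warm-started from the full-data components), and its genotypic BLUPs
    are correlated with the all-environment BLUPs.  s=1 uses the
    environment-specific genotype model directly.  Failed refits are skipped
    and counted.  With ``include_full`` a final row at s=E verifies r=1.
    """
    envs = data.environments
    E = len(envs)
    if E < 3:
        raise ValidationError("accuracy curve needs >=3 environments")
    rng = np.random.default_rng(seed)
    full = fit_joint(data, trait, pev_terms=())
    overall = full.fit.blups["genotype"]
    warm = dict(full.fit.var_components)
    rows = []
    for s in range(1, E):
        rs, skipped = [], 0
        for _ in range(n_samples):
            subset = list(rng.choice(envs, size=s, replace=False))
            try:
                if s == 1:
                    fit = fit_env_genotype_model(data, subset[0], trait)
                else:
                    sub = data.subset_environments(subset)
                    fit = fit_joint(sub, trait, pev_terms=(), start=warm).fit
                blups = fit.blups["genotype"]
                shared = blups.index.intersection(overall.index)
                rs.append(float(np.corrcoef(blups[shared], overall[shared])[0, 1]))
            except (ValidationError, FitError) as exc:
                logger.warning("subset of size %d skipped: %s", s, exc)
                skipped += 1
        rows.append(
            {"subset_size": s, "mean_r": float(np.mean(rs)) if rs else np.nan,
             "sd_r": float(np.std(rs, ddof=1)) if len(rs) > 1 else np.nan,
             "n_ok": len(rs), "n_skipped": skipped}
        )
    if include_full:
        refit = fit_joint(data, trait, pev_terms=(), start=warm).fit
        blups = refit.blups["genotype"]
        r_full = float(np.corrcoef(blups[overall.index], overall)[0, 1])
        rows.append({"subset_size": E, "mean_r": r_full, "sd_r": 0.0,
                     "n_ok": 1, "n_skipped": 0})
    curve = pd.DataFrame(rows).set_index("subset_size")
    return AccuracyCurve(curve=curve, n_samples=n_samples, seed=seed)


@dataclass
class EnvClustering:
    correlation: pd.DataFrame
    distance: pd.DataFrame
    linkage: np.ndarray
    labels: pd.Series          # environment -> cluster id at the requested cut
    n_clusters: int


def cluster_environments(
    data: MetDataset,
    trait: str,
    n_clusters: int = 3,
    distance: str = "sqrt",     # "sqrt": d = sqrt(2(1-r)); "linear": d = 1-r
    joint_vc=None,
) -> EnvClustering:
    """Ward clustering of environments from the G x E interaction BLUPs.

    The joint-model ge BLUPs are arranged genotype x environment, environment
    columns are correlated (Pearson, pairwise complete), turned into
    distances, and clustered by Ward linkage (ward.D2 semantics).  Constant
    columns have undefined correlations and are dropped with a warning.
    """
    vc = joint_vc if joint_vc is not None else fit_joint(data, trait, pev_terms=())
    ge = vc.fit.blups["gei"]
    cells = pd.DataFrame(
        [(lab.rsplit(":", 1)[0], lab.rsplit(":", 1)[1], v) for lab, v in ge.items()],
        columns=["genotype", "environment", "blup"],
    )
    mat = cells.pivot(index="genotype", columns="environment", values="blup")
    keep = mat.columns[mat.std(ddof=0) > 0]
    if len(keep) < len(mat.columns):
        logger.warning("dropping constant environment column(s): %s",
                       sorted(set(mat.columns) - set(keep)))
        mat = mat[keep]
    if mat.shape[1] < 2:
        raise ValidationError("need >=2 environments to cluster")
    corr = mat.corr()
    if distance == "sqrt":
        D = np.sqrt(np.maximum(2.0 * (1.0 - corr.to_numpy()), 0.0))
    elif distance == "linear":
        D = np.maximum(1.0 - corr.to_numpy(), 0.0)
    else:
        raise ValueError("distance must be 'sqrt' or 'linear'")
    np.fill_diagonal(D, 0.0)
    dist = pd.DataFrame(D, index=corr.index, columns=corr.columns)
    Z = hierarchy.linkage(squareform(D, checks=False), method="ward")
    labels = pd.Series(
        hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust"),
        index=corr.index, name="cluster",
    )
    return EnvClustering(
        correlation=corr, distance=dist, linkage=Z, labels=labels, n_clusters=n_clusters
    )
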