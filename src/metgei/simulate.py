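"""Synthetic multi-environment trial generator with a known-truth ledger.

The generator emits plot values

    y = mu + g_i + e_j + b_k(j) + ge_ij + beta * p + eps,

with independent Gaussian genotype, environment and block-within-environment
effects, a genotype-by-environment interaction built from an explicit
low-rank multiplicative recipe (orthonormal, doubly-centered score/loading
columns) plus optional white noise, a Uniform(0.7, 1) harvested-proportion
covariate, and residuals that may be homogeneous or per-environment.  The
default layout mirrors an advanced cassava uniform-yield-trial series:
36 genotypes, 20 location-year trials of which 3 are dropped (unbalanced),
12 of the remaining 17 with three replicates and 5 with two.

Every random draw flows from the single ``seed`` in the config, and the
realized effects are returned in a :class:`TruthLedger` so parameter-recovery
tests can compare estimates with the exact simulated truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data import MetDataset, TraitInfo, environment_label
from .errors import ConfigError

# 20 location-year trials over 11 sites and 3 seasons; 3 dropped by default,
# leaving 17 of which 5 run with two replicates (the rest with three).
_DEFAULT_LOCATIONS = tuple(f"Site{chr(ord('A') + i)}" for i in range(11))
_DEFAULT_YEARS = (2018, 2019, 2020)


def _default_trials() -> tuple[tuple[str, int], ...]:
    locs, yrs = _DEFAULT_LOCATIONS, _DEFAULT_YEARS
    trials = []
    for j, loc in enumerate(locs):
        trials.append((loc, yrs[j % 3]))          # every site appears once
        if j < 9:
            trials.append((loc, yrs[(j + 1) % 3]))  # 9 sites appear twice
    return tuple(trials[:20])


@dataclass
class SimulationConfig:
    """Stated world for the generator; defaults are the study-scale layout."""

    n_genotypes: int = 36
    trials: Sequence[tuple[str, int]] = field(default_factory=_default_trials)
    missing_trials: Sequence[tuple[str, int]] = field(
        default_factory=lambda: _default_trials()[17:]
    )
    #: replicates per kept trial keyed by environment label; unlisted -> default_reps
    reps_per_trial: Mapping[str, int] = field(default_factory=dict)
    default_reps: int = 3
    n_two_rep_trials: int = 5
    mu: float = 27.5
    var_g: float = 2.0
    var_env: float = 10.0
    var_block: float = 0.5
    var_ge_noise: float = 0.25
    var_error: float = 4.0
    error_heterogeneity: Mapping[str, float] | None = None
    K: int = 2
    lambdas: Sequence[float] | None = None   # default: fill 0.75 of GE variance, 2:1 SS split
    fw_slopes: Mapping[str, float] | None = None
    #: explicit genotype x environment interaction matrix (overrides the
    #: low-rank recipe); used to plant known structure, e.g. sign blocks
    ge_matrix: "pd.DataFrame | None" = None
    covariate_beta: float = 5.0
    trait: str = "FYLD"
    seed: int = 20180701

    def kept_trials(self) -> list[tuple[str, int]]:
        missing = set(self.missing_trials)
        return [t for t in self.trials if t not in missing]

    def environments(self) -> list[str]:
        return [environment_label(l, y) for l, y in self.kept_trials()]

    def reps_for(self, env: str, index: int) -> int:
        if env in self.reps_per_trial:
            return int(self.reps_per_trial[env])
        # first n_two_rep_trials environments (in layout order) get 2 reps
        return 2 if index < self.n_two_rep_trials else self.default_reps


@dataclass
class TruthLedger:
    """Realized effects behind one simulated dataset."""

    mu: float
    genotype_effects: pd.Series
    environment_effects: pd.Series
    block_effects: pd.Series           # index (environment, replicate)
    ge_matrix: pd.DataFrame            # genotypes x environments
    error_variances: pd.Series         # per environment
    lambdas: np.ndarray
    genotype_scores: np.ndarray        # G x K, orthonormal, column sums 0
    env_loadings: np.ndarray           # E x K
    fw_slopes: pd.Series | None = None
    covariate_beta: float = 0.0


def _centered_orthonormal(rng: np.random.Generator, n: int, k: int) -> np.ndarray:
    """k orthonormal columns of length n, each orthogonal to the ones vector."""
    A = rng.standard_normal((n, k))
    A -= A.mean(axis=0)
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))  # deterministic sign
    return Q[:, :k]


def _default_lambdas(cfg: SimulationConfig, G: int, E: int) -> np.ndarray:
    """Split 75% of a unit-total GE variance 2:1 over two axes by default.

    Mean square of the low-rank part is sum(lambda^2)/(G*E); with the default
    var_ge_noise = 0.25 the total interaction variance is ~1.
    """
    target = 0.75 * G * E
    lam2 = np.array([2.0, 1.0][: cfg.K] + [0.0] * max(0, cfg.K - 2))
    if cfg.K > 2:
        lam2 = np.linspace(2.0, 0.5, cfg.K)
    lam2 = lam2 / lam2.sum() * target
    return np.sqrt(lam2)


def _base_effects(cfg: SimulationConfig, rng: np.random.Generator):
    genotypes = [f"G{i + 1:03d}" for i in range(cfg.n_genotypes)]
    kept = cfg.kept_trials()
    envs = [environment_label(l, y) for l, y in kept]
    if len(set(envs)) != len(envs):
        raise ConfigError("duplicate (location, year) trials")
    g = pd.Series(rng.normal(0, np.sqrt(cfg.var_g), len(genotypes)), index=genotypes)
    e = pd.Series(rng.normal(0, np.sqrt(cfg.var_env), len(envs)), index=envs)
    return genotypes, kept, envs, g, e


def _assemble(cfg, rng, genotypes, kept, envs, g, e, ge, slopes=None) -> tuple[MetDataset, TruthLedger]:
    err = pd.Series(
        [cfg.error_heterogeneity.get(env, cfg.var_error) if cfg.error_heterogeneity else cfg.var_error
         for env in envs],
        index=envs,
    )
    rows = []
    block_idx, block_vals = [], []
    for j, ((loc, yr), env) in enumerate(zip(kept, envs)):
        n_rep = cfg.reps_for(env, j)
        trial = f"{yr % 100:02d}UYT{loc}"
        b = rng.normal(0, np.sqrt(cfg.var_block), n_rep)
        for r in range(1, n_rep + 1):
            block_idx.append((env, r))
            block_vals.append(b[r - 1])
            p = rng.uniform(0.7, 1.0, len(genotypes))
            eps = rng.normal(0, np.sqrt(err[env]), len(genotypes))
            y = (
                cfg.mu
                + g.to_numpy()
                + e[env]
                + b[r - 1]
                + ge.loc[:, env].to_numpy()
                + cfg.covariate_beta * p
                + eps
            )
            for i, gt in enumerate(genotypes):
                rows.append((gt, loc, yr, trial, r, p[i], y[i]))
    df = pd.DataFrame(
        rows,
        columns=["genotype", "location", "year", "trial", "replicate", "prop_harvested", cfg.trait],
    )
    data = MetDataset(df, {cfg.trait: TraitInfo(higher_is_better=True, uses_covariate=True)})
    ledger = TruthLedger(
        mu=cfg.mu,
        genotype_effects=g,
        environment_effects=e,
        block_effects=pd.Series(block_vals, index=pd.MultiIndex.from_tuples(block_idx)),
        ge_matrix=ge,
        error_variances=err,
        lambdas=np.asarray(cfg.lambdas if cfg.lambdas is not None else []),
        genotype_scores=np.empty((0, 0)),
        env_loadings=np.empty((0, 0)),
        fw_slopes=slopes,
        covariate_beta=cfg.covariate_beta,
    )
    return data, ledger


def simulate_met(config: SimulationConfig) -> tuple[MetDataset, TruthLedger]:
    """Simulate one MET dataset with low-rank + white-noise interaction."""
    rng = np.random.default_rng(config.seed)
    genotypes, kept, envs, g, e = _base_effects(config, rng)
    G, E = len(genotypes), len(envs)
    if config.ge_matrix is not None:
        ge = config.ge_matrix.reindex(index=genotypes, columns=envs)
        if ge.isna().any().any():
            raise ConfigError("ge_matrix must cover every genotype and environment")
        data, ledger = _assemble(config, rng, genotypes, kept, envs, g, e, ge)
        ledger.lambdas = np.array([])
        return data, ledger
    if config.K > min(G - 1, E - 1):
        raise ConfigError(f"K={config.K} exceeds min(G-1, E-1)={min(G - 1, E - 1)}")
    if config.K > 0:
        lam = (
            np.asarray(config.lambdas, float)
            if config.lambdas is not None
            else _default_lambdas(config, G, E)
        )
        if len(lam) != config.K:
            raise ConfigError("lambdas length must equal K")
        if np.any(np.diff(lam) > 0):
            raise ConfigError("lambdas must be non-increasing")
        alpha = _centered_orthonormal(rng, G, config.K)
        gamma = _centered_orthonormal(rng, E, config.K)
        ge_vals = alpha @ np.diag(lam) @ gamma.T
    else:
        lam = np.array([])
        alpha = np.empty((G, 0))
        gamma = np.empty((E, 0))
        ge_vals = np.zeros((G, E))
    if config.var_ge_noise > 0:
        ge_vals = ge_vals + rng.normal(0, np.sqrt(config.var_ge_noise), (G, E))
    ge = pd.DataFrame(ge_vals, index=genotypes, columns=envs)
    data, ledger = _assemble(config, rng, genotypes, kept, envs, g, e, ge)
    ledger.lambdas = lam
    ledger.genotype_scores = alpha
    ledger.env_loadings = gamma
    return data, ledger


def simulate_fw_met(config: SimulationConfig) -> tuple[MetDataset, TruthLedger]:
    """Simulate with interaction ge_ij = (beta_i - 1) * e_j + noise.

    The interaction is regression-on-the-environment structured so that
    Finlay-Wilkinson sensitivity recovery is well-posed; ``config.fw_slopes``
    (mean 1) is required.
    """
    if config.fw_slopes is None:
        raise ConfigError("fw_slopes required for simulate_fw_met")
    rng = np.random.default_rng(config.seed)
    genotypes, kept, envs, g, e = _base_effects(config, rng)
    if isinstance(config.fw_slopes, pd.Series):
        slopes = config.fw_slopes
    elif isinstance(config.fw_slopes, Mapping):
        slopes = pd.Series(dict(config.fw_slopes))
    else:  # sequence, in genotype order
        slopes = pd.Series(list(config.fw_slopes), index=genotypes[: len(list(config.fw_slopes))])
    slopes = slopes.reindex(genotypes)
    if slopes.isna().any():
        raise ConfigError("fw_slopes must cover every genotype")
    if abs(slopes.mean() - 1.0) > 1e-12:
        raise ConfigError("fw_slopes must average to 1")
    ge_vals = np.outer(slopes.to_numpy() - 1.0, e.to_numpy())
    if config.var_ge_noise > 0:
        ge_vals = ge_vals + rng.normal(0, np.sqrt(config.var_ge_noise), ge_vals.shape)
    ge = pd.DataFrame(ge_vals, index=genotypes, columns=envs)
    return _assemble(config, rng, genotypes, kept, envs, g, e, ge, slopes=slopes)
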