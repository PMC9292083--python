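"""Data model and I/O for plot-level multi-environment trial (MET) data.

A MET dataset is long-format: one row per field plot, carrying the design
factors (genotype, location, year, trial, replicate), the proportion of the
plant stand actually harvested (a covariate for yield traits), and one or
more trait observations.  An *environment* is a location x cropping-season
combination, labelled ``<Location><YY>`` (e.g. ``Ibadan19``).

Two in-memory containers are exposed:

``MetDataset``
    the long table plus a per-trait registry (direction of merit, whether the
    harvested-proportion covariate applies).
``TwoWayMeans``
    a genotype x environment matrix of adjusted means with an explicit
    missing mask, the common input of the Finlay-Wilkinson, AMMI, GGE and
    superiority analyses.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import SchemaError, ValidationError

logger = logging.getLogger(__name__)

#: canonical column names of the long format
DESIGN_COLUMNS = ("genotype", "location", "year", "trial", "replicate", "prop_harvested")

DEFAULT_SCHEMA = {c: c for c in DESIGN_COLUMNS}


def environment_label(location: str, year: int) -> str:
    """Environment identifier ``<Location><YY>`` (e.g. ``Ibadan19`` for 2019)."""
    return f"{location}{int(year) % 100:02d}"


@dataclass
class TraitInfo:
    """Registry entry for one trait."""

    higher_is_better: bool = True
    uses_covariate: bool = True


@dataclass(frozen=True)
class PlotRecord:
    """One field-plot observation."""

    genotype: str
    location: str
    year: int
    trial: str
    replicate: int
    prop_harvested: float
    traits: Mapping[str, float]

    @property
    def environment(self) -> str:
        return environment_label(self.location, self.year)


class MetDataset:
    """Plot-level MET data: a validated long-format table plus trait registry.

    Parameters
    ----------
    df
        Long-format frame with the columns in :data:`DESIGN_COLUMNS` plus one
        column per trait.  An ``environment`` column is derived if absent.
    trait_registry
        Maps trait name to :class:`TraitInfo`.  Traits not listed get the
        default (higher is better, covariate applies).
    """

    def __init__(self, df: pd.DataFrame, trait_registry: Mapping[str, TraitInfo] | None = None):
        df = df.copy()
        missing = [c for c in DESIGN_COLUMNS if c not in df.columns and c != "prop_harvested"]
        if missing:
            raise SchemaError(f"missing required column(s): {', '.join(missing)}")
        if "prop_harvested" not in df.columns:
            df["prop_harvested"] = np.nan
        df["year"] = df["year"].astype(int)
        df["replicate"] = df["replicate"].astype(int)
        df["environment"] = [
            environment_label(l, y) for l, y in zip(df["location"], df["year"])
        ]
        trait_cols = [c for c in df.columns if c not in DESIGN_COLUMNS and c != "environment"]
        if not trait_cols:
            raise SchemaError("no trait columns found")
        registry = {t: TraitInfo() for t in trait_cols}
        if trait_registry:
            registry.update({k: v for k, v in trait_registry.items() if k in registry})
        dup = df.duplicated(subset=["trial", "replicate", "genotype"], keep=False)
        if dup.any():
            offenders = (
                df.loc[dup, ["trial", "replicate", "genotype"]]
                .drop_duplicates()
                .to_records(index=False)
                .tolist()
            )
            raise ValidationError(f"duplicate (trial, replicate, genotype) plots: {offenders}")
        p = df["prop_harvested"].dropna()
        if ((p < 0) | (p > 1)).any():
            raise ValidationError("prop_harvested outside [0, 1]")
        self.df = df.reset_index(drop=True)
        self.trait_registry = registry

    # -- basic accessors -------------------------------------------------
    @property
    def traits(self) -> list[str]:
        return list(self.trait_registry)

    @property
    def genotypes(self) -> list[str]:
        return sorted(self.df["genotype"].unique())

    @property
    def environments(self) -> list[str]:
        return sorted(self.df["environment"].unique())

    @property
    def trials(self) -> list[str]:
        return sorted(self.df["trial"].unique())

    def records(self) -> Iterator[PlotRecord]:
        for _, row in self.df.iterrows():
            yield PlotRecord(
                genotype=row["genotype"],
                location=row["location"],
                year=int(row["year"]),
                trial=row["trial"],
                replicate=int(row["replicate"]),
                prop_harvested=float(row["prop_harvested"]),
                traits={t: row[t] for t in self.trait_registry},
            )

    def subset_environments(self, envs: Sequence[str]) -> "MetDataset":
        sub = self.df[self.df["environment"].isin(envs)]
        return MetDataset(sub.drop(columns=["environment"]), self.trait_registry)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return (
            f"MetDataset({len(self.df)} plots, {len(self.genotypes)} genotypes, "
            f"{len(self.environments)} environments, traits={self.traits})"
        )


class TwoWayMeans:
    """Genotype x environment mean table with a missing mask.

    Stored as a DataFrame (genotypes as rows, environments as columns) with
    NaN marking empty cells.
    """

    def __init__(self, table: pd.DataFrame):
        self.table = table.astype(float)

    @property
    def genotypes(self) -> list[str]:
        return list(self.table.index)

    @property
    def environments(self) -> list[str]:
        return list(self.table.columns)

    @property
    def means(self) -> np.ndarray:
        return self.table.to_numpy()

    @property
    def missing_mask(self) -> np.ndarray:
        return np.isnan(self.means)

    @property
    def is_complete(self) -> bool:
        return not self.missing_mask.any()

    def to_csv(self, path) -> None:
        self.table.to_csv(path, na_rep="")

    @classmethod
    def from_csv(cls, path) -> "TwoWayMeans":
        return cls(pd.read_csv(path, index_col=0))

    def __repr__(self) -> str:
        g, e = self.table.shape
        return f"TwoWayMeans({g} genotypes x {e} environments, {int(self.missing_mask.sum())} missing)"


def read_met_csv(
    path,
    schema: Mapping[str, str] | None = None,
    traits: Mapping[str, str] | Sequence[str] | None = None,
    trait_registry: Mapping[str, TraitInfo] | None = None,
) -> MetDataset:
    """Read a long-format MET CSV.

    ``schema`` maps canonical design-column names to the file's column names;
    ``traits`` maps trait names to file columns (or lists columns used as-is).
    Unparseable trait values become missing (NaN), never dropped rows.
    """
    raw = pd.read_csv(path)
    schema = {**DEFAULT_SCHEMA, **(schema or {})}
    out = {}
    for canon in DESIGN_COLUMNS:
        col = schema.get(canon, canon)
        if col not in raw.columns:
            if canon == "prop_harvested":
                continue
            raise SchemaError(f"required column '{canon}' (file column '{col}') not found")
        out[canon] = raw[col]
    df = pd.DataFrame(out)
    if traits is None:
        used = set(schema.values())
        trait_map = {c: c for c in raw.columns if c not in used}
    elif isinstance(traits, Mapping):
        trait_map = dict(traits)
    else:
        trait_map = {t: t for t in traits}
    if not trait_map:
        raise SchemaError("no trait columns identified")
    for name, col in trait_map.items():
        if col not in raw.columns:
            raise SchemaError(f"trait column '{col}' not found")
        df[name] = pd.to_numeric(raw[col], errors="coerce")
    return MetDataset(df, trait_registry)


def write_met_csv(data: MetDataset, path) -> None:
    """Write the long table back out (canonical column names, RFC-4180)."""
    cols = [c for c in DESIGN_COLUMNS] + list(data.trait_registry)
    data.df[cols].to_csv(path, index=False)


def _env_blues(sub: pd.DataFrame, trait: str, use_covariate: bool) -> pd.Series:
    """Genotype BLUEs within one environment.

    Fixed-effects least squares: full genotype dummies, sum-coded replicate
    effects, and (optionally) the harvested-proportion covariate centered at
    its environment mean, so the returned values sit on the trait scale.
    """
    sub = sub.dropna(subset=[trait])
    gts = sorted(sub["genotype"].unique())
    g_codes = pd.Categorical(sub["genotype"], categories=gts).codes
    n, G = len(sub), len(gts)
    Xg = np.zeros((n, G))
    Xg[np.arange(n), g_codes] = 1.0
    blocks = [Xg]
    reps = sorted(sub["replicate"].unique())
    if len(reps) > 1:
        r_codes = pd.Categorical(sub["replicate"], categories=reps).codes
        Xr = np.zeros((n, len(reps) - 1))
        for j in range(len(reps) - 1):
            Xr[r_codes == j, j] = 1.0
        Xr[r_codes == len(reps) - 1, :] = -1.0  # sum-to-zero coding
        blocks.append(Xr)
    if use_covariate:
        p = sub["prop_harvested"].to_numpy(float)
        if np.isnan(p).any():
            warnings.warn("missing prop_harvested treated as environment mean")
            p = np.where(np.isnan(p), np.nanmean(p), p)
        blocks.append((p - p.mean())[:, None])
    X = np.hstack(blocks)
    beta, *_ = np.linalg.lstsq(X, sub[trait].to_numpy(float), rcond=None)
    return pd.Series(beta[:G], index=gts)


def adjusted_means(data: MetDataset, trait: str, method: str = "blue") -> TwoWayMeans:
    """Two-way genotype x environment adjusted-mean table for one trait.

    ``method='blue'`` (default) fits, per environment, genotype as fixed with
    replicate effects and the centered harvested-proportion covariate (when
    the trait uses it), returning genotype BLUEs.  ``method='raw'`` returns
    plain cell means.  Environments with a single genotype are dropped with a
    warning; empty cells are flagged missing.
    """
    if trait not in data.trait_registry:
        raise KeyError(f"trait '{trait}' not in dataset (have {data.traits})")
    use_cov = data.trait_registry[trait].uses_covariate
    cols = {}
    for env, sub in data.df.groupby("environment"):
        sub = sub.dropna(subset=[trait])
        if sub["genotype"].nunique() < 2:
            logger.warning("environment %s has <2 genotypes with data; dropped", env)
            continue
        if method == "raw":
            cols[env] = sub.groupby("genotype")[trait].mean()
        elif method == "blue":
            cols[env] = _env_blues(sub, trait, use_cov)
        else:
            raise ValueError(f"unknown method '{method}'")
    if not cols:
        raise ValidationError(f"no analyzable environment for trait '{trait}'")
    table = pd.DataFrame(cols).reindex(index=data.genotypes, columns=sorted(cols))
    return TwoWayMeans(table)
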