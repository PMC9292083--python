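"""End-to-end pipeline: QC -> joint model -> FW -> AMMI -> GGE -> stability -> TPE.

`run_report` chains every stage on one dataset in the standard MET-analysis
order, writing each stage's tables (CSV) and summaries (JSON) into an output
directory together with a manifest recording the seed, stage timings and the
emitted files.  A YAML run configuration maps onto :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .ammi import asv, delineate_mega_envs, fit_ammi, gsi, impute_missing_em
from .data import MetDataset, adjusted_means, read_met_csv
from .errors import MetError
from .fw import fit_fw, fw_anova
from .gge import fit_gge, which_won_where
from .joint import (fit_joint, h2_across, harmonic_mean_reps, lrt_error_heterogeneity,
                    lrt_gei, partition_gei)
from .single_trial import fit_all_trials, qc_filter, summaries_frame
from .stability import stability_report, superiority_index
from .tpe import accuracy_curve, cluster_environments, rank_environments

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    input: str | None = None            # CSV path; alternatively pass a dataset
    traits: list[str] = field(default_factory=list)
    out_dir: str = "results"
    qc_thresholds: dict = field(default_factory=dict)
    heterogeneous_error: bool = True
    mixture_null: bool = True
    run_partition: bool = True
    ammi_K: int = 2
    asv_scaling_exponent: float = 0.5
    impute: bool = True
    tpe_n_samples: int = 50
    tpe_n_clusters: int = 3
    run_accuracy_curve: bool = True
    seed: int = 1

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _stage_seed(seed: int, k: int) -> int:
    return int(np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31))


def run_report(config: RunConfig, data: MetDataset | None = None) -> dict:
    """Run the full analysis; returns (and writes) the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": config.seed, "stages": {}, "files": []}

    def emit(name: str, path: Path):
        manifest["files"].append(str(path))

    def done(stage: str, t0: float):
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

    try:
        if data is None:
            data = read_met_csv(config.input)
        traits = config.traits or data.traits
        for trait in traits:
            tdir = out / trait
            tdir.mkdir(exist_ok=True)

            # -- QC ------------------------------------------------------
            t0 = time.perf_counter()
            summaries = fit_all_trials(data, trait)
            kept, removed = qc_filter(summaries, config.qc_thresholds)
            summaries_frame(summaries).to_csv(tdir / "trial_qc.csv", index=False)
            emit("qc", tdir / "trial_qc.csv")
            verdict = {
                "kept": [s.trial for s in kept],
                "removed": [s.trial for s in removed],
            }
            (tdir / "qc_verdict.json").write_text(json.dumps(verdict, indent=2))
            emit("qc", tdir / "qc_verdict.json")
            done(f"{trait}/qc", t0)
            if not kept:
                manifest["stages"][f"{trait}/qc"] = "all trials failed QC; stopping"
                raise MetError(f"all trials failed QC for {trait}")
            clean = data.subset_environments([s.environment for s in kept])

            # -- joint model --------------------------------------------
            t0 = time.perf_counter()
            vc = fit_joint(clean, trait, heterogeneous_error=config.heterogeneous_error)
            vc.as_frame().to_csv(tdir / "variance_components.csv")
            emit("joint", tdir / "variance_components.csv")
            reps = [s.n_reps for s in kept]
            r_eff = harmonic_mean_reps(reps)
            n_env = clean.df["environment"].nunique()
            lrts = {
                "gei": vars(lrt_gei(clean, trait, mixture_null=config.mixture_null)),
                "error_heterogeneity": vars(lrt_error_heterogeneity(clean, trait)),
                "h2_across": h2_across(vc, n_env, r_eff),
                "harmonic_mean_reps": r_eff,
            }
            (tdir / "joint_tests.json").write_text(json.dumps(lrts, indent=2, default=float))
            emit("joint", tdir / "joint_tests.json")
            if config.run_partition and clean.df["location"].nunique() > 1:
                part = partition_gei(clean, trait)
                part.as_frame().to_csv(tdir / "gei_partition.csv")
                emit("joint", tdir / "gei_partition.csv")
            done(f"{trait}/joint", t0)

            # -- two-way means & FW -------------------------------------
            t0 = time.perf_counter()
            table = adjusted_means(clean, trait)
            table.to_csv(tdir / "two_way_means.csv")
            emit("means", tdir / "two_way_means.csv")
            if config.impute and not table.is_complete:
                table = impute_missing_em(table, K=config.ammi_K)
            fw = fit_fw(table)
            fw.genotype_rows.to_csv(tdir / "fw_genotypes.csv")
            emit("fw", tdir / "fw_genotypes.csv")
            (tdir / "fw_summary.json").write_text(
                json.dumps(fw.trait_summaries, indent=2)
            )
            emit("fw", tdir / "fw_summary.json")
            if table.is_complete:
                fw_anova(fw).to_csv(tdir / "fw_anova.csv")
                emit("fw", tdir / "fw_anova.csv")
            done(f"{trait}/fw", t0)

            # -- AMMI ----------------------------------------------------
            t0 = time.perf_counter()
            afit = fit_ammi(table, K=config.ammi_K)
            afit.ss_table.to_csv(tdir / "ammi_anova.csv")
            emit("ammi", tdir / "ammi_anova.csv")
            a = asv(afit, config.asv_scaling_exponent)
            direction = data.trait_registry[trait].higher_is_better
            stab = gsi(afit, a, higher_is_better=direction)
            stab.table.to_csv(tdir / "ammi_stability.csv")
            emit("ammi", tdir / "ammi_stability.csv")
            mega = delineate_mega_envs(afit, higher_is_better=direction)
            (tdir / "mega_environments.json").write_text(
                json.dumps(mega.groups, indent=2)
            )
            emit("ammi", tdir / "mega_environments.json")
            done(f"{trait}/ammi", t0)

            # -- GGE -----------------------------------------------------
            t0 = time.perf_counter()
            gfit = fit_gge(table)
            gfit.ss_table.to_csv(tdir / "gge_anova.csv")
            emit("gge", tdir / "gge_anova.csv")
            www = which_won_where(gfit)
            (tdir / "which_won_where.json").write_text(
                json.dumps({"hull": www.hull_vertices, "sectors": www.sectors}, indent=2)
            )
            emit("gge", tdir / "which_won_where.json")
            done(f"{trait}/gge", t0)

            # -- stability ----------------------------------------------
            t0 = time.perf_counter()
            sup = superiority_index(table, higher_is_better=direction)
            report, spearman = stability_report(fw, stab, sup)
            report.to_csv(tdir / "stability_report.csv")
            spearman.to_csv(tdir / "stability_spearman.csv")
            emit("stability", tdir / "stability_report.csv")
            emit("stability", tdir / "stability_spearman.csv")
            done(f"{trait}/stability", t0)

            # -- TPE -----------------------------------------------------
            t0 = time.perf_counter()
            ranks = rank_environments(clean, trait)
            ranks.to_csv(tdir / "tpe_env_ranks.csv")
            emit("tpe", tdir / "tpe_env_ranks.csv")
            clus = cluster_environments(clean, trait, n_clusters=config.tpe_n_clusters)
            clus.labels.to_csv(tdir / "tpe_clusters.csv")
            emit("tpe", tdir / "tpe_clusters.csv")
            if config.run_accuracy_curve:
                curve = accuracy_curve(
                    clean, trait, n_samples=config.tpe_n_samples,
                    seed=_stage_seed(config.seed, 7),
                )
                curve.curve.to_csv(tdir / "tpe_accuracy_curve.csv")
                emit("tpe", tdir / "tpe_accuracy_curve.csv")
            done(f"{trait}/tpe", t0)
        manifest["status"] = "complete"
    except Exception as exc:  # record partial completion, then re-raise
        manifest["status"] = f"failed: {exc}"
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
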