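"""Simulate the analysis dataset: a study-scale cassava uniform-yield-trial
series (36 clones, 20 location-year trials of which 3 dropped, replicates
3/2, low-rank GEI plus noise) and write it with its truth ledger."""

import json

import numpy as np

from _common import DATA_CSV, SEED, outdir

from metgei import SimulationConfig, simulate_met, write_met_csv

cfg = SimulationConfig(seed=SEED)
data, truth = simulate_met(cfg)
DATA_CSV.parent.mkdir(parents=True, exist_ok=True)
write_met_csv(data, DATA_CSV)

out = outdir("data")
truth.ge_matrix.to_csv(out / "truth_ge_matrix.csv")
summary = {
    "seed": SEED,
    "n_plots": len(data),
    "n_genotypes": len(data.genotypes),
    "n_environments": len(data.environments),
    "variances": {"genotype": cfg.var_g, "environment": cfg.var_env,
                  "block": cfg.var_block, "ge_noise": cfg.var_ge_noise,
                  "error": cfg.var_error},
    "lambdas": list(np.round(truth.lambdas, 4)),
    "realized": {
        "genotype": float(truth.genotype_effects.var(ddof=1)),
        "environment": float(truth.environment_effects.var(ddof=1)),
        "block": float(truth.block_effects.var(ddof=1)),
        "ge_mean_square": float((truth.ge_matrix.to_numpy() ** 2).mean()),
    },
}
(out / "truth_summary.json").write_text(json.dumps(summary, indent=2))

print(f"wrote {DATA_CSV}: {len(data)} plots, "
      f"{len(data.genotypes)} genotypes x {len(data.environments)} environments")
print("realized component variances:", {k: round(v, 3) for k, v in summary["realized"].items()})
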