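"""Finlay-Wilkinson sensitivity regression on standardized adjusted means:
per-clone intercept/slope/MSE with stability ranking, the joint-regression
ANOVA, and trait-level slope/MSE summaries."""

import json

from _common import TRAIT, load_or_simulate, outdir

from metgei import adjusted_means, fit_fw, fw_anova

data = load_or_simulate()
table = adjusted_means(data, TRAIT)
fit = fit_fw(table)

out = outdir("fw")
fit.genotype_rows.to_csv(out / "fw_genotypes.csv")
(out / "fw_summary.json").write_text(json.dumps(fit.trait_summaries, indent=2))
an = fw_anova(fit)
an.to_csv(out / "fw_anova.csv")

top = fit.genotype_rows.sort_values("rank_slope").head(5)
print("five least sensitive (lowest slope) clones:")
print(top[["slope", "mse", "rank_slope"]].round(3).to_string())
print("\ntrait summaries:", {k: round(v, 4) for k, v in fit.trait_summaries.items()})
print("\njoint-regression ANOVA:")
print(an.round(3).to_string())
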