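"""AMMI analysis: additive main effects + SVD of the doubly-centered
interaction, ASV and genotype selection index, AMMI-2 biplot, and
mega-environment delineation by winning clone."""

import json

import matplotlib.pyplot as plt

from _common import TRAIT, load_or_simulate, outdir

from metgei import adjusted_means, asv, delineate_mega_envs, fit_ammi, gsi
from metgei.plots import ammi_biplot

data = load_or_simulate()
table = adjusted_means(data, TRAIT)
fit = fit_ammi(table, K=2)

out = outdir("ammi")
fit.ss_table.to_csv(out / "ammi_anova.csv")
print("AMMI ANOVA (%TSS / %interaction):")
print(fit.ss_table.round(2).to_string())

stab = gsi(fit, asv(fit))
stab.table.to_csv(out / "ammi_stability.csv")
print("\ntop 5 clones by genotype selection index (yield rank + ASV rank):")
print(stab.table.head(5).round(3).to_string())

mega = delineate_mega_envs(fit)
(out / "mega_environments.json").write_text(json.dumps(mega.groups, indent=2))
print(f"\n{mega.n_mega_environments} mega-environment(s):")
for winner, envs in mega.groups.items():
    print(f"  {winner}: {', '.join(envs)}")

figdir = outdir("figures")
fig, ax = plt.subplots(figsize=(7, 6))
ammi_biplot(fit, ax=ax)
fig.savefig(figdir / "ammi2_biplot.png", dpi=150)
print(f"\nbiplot written to {figdir / 'ammi2_biplot.png'}")
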