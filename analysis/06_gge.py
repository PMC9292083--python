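"""GGE (site regression) analysis: environment-centered SVD, symmetric-
scaling biplot coordinates, and which-won-where sectors."""

import json

import matplotlib.pyplot as plt

from _common import TRAIT, load_or_simulate, outdir

from metgei import adjusted_means, biplot_coords, fit_gge, which_won_where
from metgei.plots import gge_polygon_plot

data = load_or_simulate()
table = adjusted_means(data, TRAIT)
fit = fit_gge(table)

out = outdir("gge")
fit.ss_table.to_csv(out / "gge_anova.csv")
print("GGE ANOVA (%TSS / %GGE):")
print(fit.ss_table.round(2).to_string())

F, H = biplot_coords(fit)
F.to_csv(out / "genotype_coords.csv")
H.to_csv(out / "environment_coords.csv")

www = which_won_where(fit)
(out / "which_won_where.json").write_text(json.dumps(
    {"hull": www.hull_vertices, "sectors": www.sectors}, indent=2))
print(f"\nhull vertices: {', '.join(www.hull_vertices)}")
print("sector winners:")
for winner, envs in www.sectors.items():
    print(f"  {winner}: {', '.join(envs)}")

figdir = outdir("figures")
fig, ax = plt.subplots(figsize=(7, 6))
gge_polygon_plot(www, ax=ax)
fig.savefig(figdir / "gge_polygon.png", dpi=150)
print(f"\npolygon view written to {figdir / 'gge_polygon.png'}")
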