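"""Representativeness of the target population of environments: per-
environment BLUP correlation with the TPE and Cullis heritability (rank-sum
ordered), the environment-subset accuracy curve, and Ward clustering of
environments from the G x E BLUPs."""

import matplotlib.pyplot as plt

from _common import SEED, TRAIT, load_or_simulate, outdir

from metgei import accuracy_curve, cluster_environments, rank_environments
from metgei.plots import accuracy_curve_plot, dendrogram_plot

data = load_or_simulate()
out = outdir("tpe")

ranks = rank_environments(data, TRAIT)
ranks.to_csv(out / "env_ranks.csv")
print("environments ranked by (BLUP correlation with TPE, Cullis H2):")
print(ranks.round(3).to_string())

curve = accuracy_curve(data, TRAIT, n_samples=10, seed=SEED)
curve.curve.to_csv(out / "accuracy_curve.csv")
print("\naccuracy curve (mean BLUP correlation vs number of sampled environments):")
print(curve.curve.round(3).to_string())

clus = cluster_environments(data, TRAIT, n_clusters=3)
clus.labels.to_csv(out / "env_clusters.csv")
print("\n3-cluster Ward grouping of environments (from G x E BLUPs):")
for c in sorted(clus.labels.unique()):
    print(f"  cluster {c}: {', '.join(clus.labels.index[clus.labels == c])}")

figdir = outdir("figures")
fig, ax = plt.subplots(figsize=(6, 4))
accuracy_curve_plot(curve, ax=ax)
fig.tight_layout()
fig.savefig(figdir / "tpe_accuracy_curve.png", dpi=150)
fig2, ax2 = plt.subplots(figsize=(7, 4))
dendrogram_plot(clus, ax=ax2)
fig2.tight_layout()
fig2.savefig(figdir / "tpe_dendrogram.png", dpi=150)
print(f"\nfigures written to {figdir}")
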