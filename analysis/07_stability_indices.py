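"""Cross-model stability: Lin-Binns cultivar superiority index with its
genetic/GEI decomposition, merged with the Finlay-Wilkinson and AMMI
stability measures, plus Spearman agreement among the measures."""

from _common import TRAIT, load_or_simulate, outdir

from metgei import (adjusted_means, asv, fit_ammi, fit_fw, gsi, stability_report,
                    superiority_index)

data = load_or_simulate()
table = adjusted_means(data, TRAIT)

fw = fit_fw(table)
afit = fit_ammi(table, K=2)
stab = gsi(afit, asv(afit))
sup = superiority_index(table)

out = outdir("stability")
sup.table.to_csv(out / "superiority_index.csv")
print("top 5 clones by superiority index P_i (consistently near the per-"
      "environment best):")
print(sup.table.head(5).round(3).to_string())

report, spearman = stability_report(fw, stab, sup)
report.to_csv(out / "stability_report.csv")
spearman.to_csv(out / "stability_spearman.csv")
print("\nSpearman correlations among stability measures:")
print(spearman.round(2).to_string())
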