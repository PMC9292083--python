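"""Single-trial mixed-model QC: per-trial CV%, plot heritability and BLUP
accuracy, and the removal verdict at the standard thresholds
(H2 < 0.1, Ac < 0.4, CV > 40.5 remove)."""

import json

from _common import TRAIT, load_or_simulate, outdir

from metgei import fit_all_trials, qc_filter
from metgei.single_trial import summaries_frame

data = load_or_simulate()
summaries = fit_all_trials(data, TRAIT)
kept, removed = qc_filter(summaries)

out = outdir("qc")
frame = summaries_frame(summaries)
frame.to_csv(out / "trial_qc.csv", index=False)
(out / "qc_verdict.json").write_text(json.dumps(
    {"kept": [s.trial for s in kept], "removed": [s.trial for s in removed]}, indent=2))

print(frame[["trial", "n_reps", "trait_mean", "cv_pct", "h2_plot", "accuracy",
             "passed_qc"]].round(3).to_string(index=False))
print(f"\n{len(kept)} of {len(summaries)} trials pass QC "
      f"(H2 range {frame.h2_plot.min():.2f}-{frame.h2_plot.max():.2f}, "
      f"CV range {frame.cv_pct.min():.1f}-{frame.cv_pct.max():.1f}%)")
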