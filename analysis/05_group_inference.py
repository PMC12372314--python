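#!/usr/bin/env python
"""The preregistered battery: covariate-adjusted group models for IRC and
reference similarity, specialization-similarity association models,
heterogeneity t-tests, brain-behavior models, null-evidence Bayes factors,
and the two-test Bonferroni correction."""
import argparse
from pathlib import Path

import pandas as pd

from socialbrain import io, run_hypothesis_battery

parser = argparse.ArgumentParser()
parser.add_argument("--base", type=Path, default=Path("results/analysis"))
args = parser.parse_args()

metrics = pd.read_csv(args.base / "metrics.tsv", sep="\t").set_index("subject_id")
cohort = pd.read_csv(args.base / "cohort" / "cohort.csv").set_index("subject_id")
data = metrics.join(cohort, how="inner")

battery = run_hypothesis_battery(data)
battery.to_frame().to_csv(args.base / "battery.tsv", sep="\t", index=False)
io.write_json(
    {
        "models": {
            name: {"terms": res.terms.to_dict(orient="index"), "n": res.n,
                   "pruned": res.pruned}
            for name, res in battery.models.items()
        },
        "ttests": {name: vars(res) for name, res in battery.ttests.items()},
        "bayes_bf01": battery.bayes,
        "bonferroni_alpha": battery.bonferroni_alpha,
    },
    args.base / "battery.json",
)

for name, res in battery.models.items():
    focal = "group" if "group" in res.terms.index else res.terms.index[-1]
    row = res.term(focal)
    print(f"{name:>24s}  {focal}: t={row['t']:+.2f} p={row['p']:.4f} d={row['d']:+.2f}"
          + (f"  pruned={res.pruned}" if res.pruned else ""))
for name, res in battery.ttests.items():
    print(f"{name:>24s}  diff={res.mean_diff:+.3f} t({res.df:.1f})={res.t:+.2f} "
          f"p={res.p:.2e} d={res.d:+.2f}")
if battery.bayes:
    for name, bf in battery.bayes.items():
        print(f"{name:>24s}  BF01={bf:.2f} (BIC approximation)")
print(f"full tables -> {args.base / 'battery.tsv'}")
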