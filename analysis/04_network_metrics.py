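#!/usr/bin/env python
"""Dependent variables per subject: within/across-network IRC (Fisher-z
means over 15/21/42 ROI pairs), similarity to the (leave-one-out) NT
reference average, within/across-group pairwise similarity, and the T04
event response magnitude."""
import argparse
from pathlib import Path

import pandas as pd

from socialbrain import io
from socialbrain.pipeline import compute_metrics_table

parser = argparse.ArgumentParser()
parser.add_argument("--base", type=Path, default=Path("results/analysis"))
parser.add_argument("--tr", type=float, default=0.72)
args = parser.parse_args()

cohort = pd.read_csv(args.base / "cohort" / "cohort.csv").set_index("subject_id")
atlas = io.read_atlas(args.base / "cohort" / "atlas.tsv")
prepped_dir = args.base / "prepped"
kept = sorted(p.name.replace("_timecourses.tsv", "") for p in prepped_dir.glob("*_timecourses.tsv"))

prepped, fd_means, n_censored = {}, {}, {}
for sid in kept:
    censor = io.read_mask(args.base / "motion_qc" / f"{sid}_mask.tsv")
    prepped[sid] = io.read_timecourses(
        prepped_dir / f"{sid}_timecourses.tsv", atlas, args.tr, censor
    )
    fd_means[sid] = io.read_fd(args.base / "motion_qc" / f"{sid}_fd.tsv").mean_fd
    n_censored[sid] = censor.n_censored

window = dict((label, (s, e)) for label, s, e in io.read_events(args.base / "cohort" / "events.tsv"))["T04"]
metrics = compute_metrics_table(prepped, cohort["group"], "NT", window)
metrics["mean_fd"] = pd.Series(fd_means)
metrics["n_censored"] = pd.Series(n_censored)
metrics.to_csv(args.base / "metrics.tsv", sep="\t")

by = metrics.join(cohort[["group"]]).groupby("group")
for col in ("within_tom_z", "within_pain_z", "across_z", "sim_nt_tom_z"):
    means = by[col].mean()
    print(f"{col}: " + ", ".join(f"{g} m={v:.3f}" for g, v in means.items()))
print(f"metrics for {len(metrics)} subjects -> {args.base / 'metrics.tsv'}")
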