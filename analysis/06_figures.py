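#!/usr/bin/env python
"""Figures: group-mean network timecourses and metric boxplots (PNG)."""
import argparse
from pathlib import Path

import pandas as pd

from socialbrain import io
from socialbrain.report import make_plots

parser = argparse.ArgumentParser()
parser.add_argument("--base", type=Path, default=Path("results/analysis"))
parser.add_argument("--tr", type=float, default=0.72)
args = parser.parse_args()

cohort = pd.read_csv(args.base / "cohort" / "cohort.csv").set_index("subject_id")
atlas = io.read_atlas(args.base / "cohort" / "atlas.tsv")
metrics = pd.read_csv(args.base / "metrics.tsv", sep="\t").set_index("subject_id")

prepped = {}
for path in sorted((args.base / "prepped").glob("*_timecourses.tsv")):
    sid = path.name.replace("_timecourses.tsv", "")
    censor = io.read_mask(args.base / "motion_qc" / f"{sid}_mask.tsv")
    prepped[sid] = io.read_timecourses(path, atlas, args.tr, censor)

out = args.base / "figures"
out.mkdir(parents=True, exist_ok=True)
written = make_plots(prepped, cohort.loc[list(prepped), "group"], metrics, out)
print("wrote " + ", ".join(str(p) for p in written))
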