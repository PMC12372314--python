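#!/usr/bin/env python
"""Temporal prep of surviving subjects: interpolate censored artifacts,
100 s Butterworth high-pass, z-score. Writes prepped wide TSVs."""
import argparse
from pathlib import Path

import pandas as pd

from socialbrain import io, prep_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--base", type=Path, default=Path("results/analysis"))
parser.add_argument("--tr", type=float, default=0.72)
args = parser.parse_args()

cohort = pd.read_csv(args.base / "cohort" / "cohort.csv").set_index("subject_id")
atlas = io.read_atlas(args.base / "cohort" / "atlas.tsv")
flags = io.read_json(args.base / "motion_qc" / "exclusion_report.json")["flags"]
kept = [s for s in cohort.index if not any(flags[s].values())]

out = args.base / "prepped"
out.mkdir(parents=True, exist_ok=True)
for sid in kept:
    censor = io.read_mask(args.base / "motion_qc" / f"{sid}_mask.tsv")
    tc = io.read_timecourses(
        args.base / "cohort" / "timecourses" / f"{sid}_timecourses.tsv",
        atlas, args.tr, censor,
    )
    io.write_timecourses(prep_pipeline(tc), out / f"{sid}_timecourses.tsv")
print(f"prepped {len(kept)} subjects into {out} "
      "(order: interpolate -> highpass -> zscore; censor masks retained)")
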