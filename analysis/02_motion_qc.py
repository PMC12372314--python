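#!/usr/bin/env python
"""Motion QC: filtered framewise displacement, censoring, exclusion, matching.

Reads the simulated motion traces, computes FDfilt4 (band-stop 0.31-0.43 Hz,
lag-4 differences), censors FD > 0.5 mm with a +-2 TR pad, flags per-site
IQR outliers and subjects with > 1/3 of the scan censored, then iteratively
matches the groups on mean FD and censored-TR counts.
"""
import argparse
from pathlib import Path

import pandas as pd

from socialbrain import compute_fd_filt4, detect_artifacts, exclude_subjects, io, match_groups_on_motion

parser = argparse.ArgumentParser()
parser.add_argument("--base", type=Path, default=Path("results/analysis"))
parser.add_argument("--tr", type=float, default=0.72)
args = parser.parse_args()

cohort = pd.read_csv(args.base / "cohort" / "cohort.csv").set_index("subject_id")
out = args.base / "motion_qc"
out.mkdir(parents=True, exist_ok=True)

fd_by, mask_by = {}, {}
for sid in cohort.index:
    trace = io.read_motion(args.base / "cohort" / "motion" / f"{sid}_motion.tsv", args.tr)
    fd_by[sid] = compute_fd_filt4(trace)
    mask_by[sid] = detect_artifacts(fd_by[sid])
    io.write_fd(fd_by[sid], out / f"{sid}_fd.tsv")
    io.write_mask(mask_by[sid], out / f"{sid}_mask.tsv")

report = exclude_subjects(fd_by, mask_by, dict(cohort["site"]))
kept = report.kept
print(f"excluded {len(report.excluded)} of {len(cohort)} subjects "
      f"(per-site thresholds {report.site_thresholds})")

qc = pd.DataFrame(
    {
        "mean_fd": {s: fd_by[s].mean_fd for s in kept},
        "n_censored": {s: float(mask_by[s].n_censored) for s in kept},
    }
)
removed = match_groups_on_motion(qc, cohort.loc[kept, "group"])
report.flags.loc[removed, "matched_removed"] = True
print(f"matching removed {len(removed)} subjects: {removed or 'none'}")

io.write_json(
    {
        "flags": {s: {c: bool(v) for c, v in r.items()} for s, r in report.flags.iterrows()},
        "site_thresholds": report.site_thresholds,
    },
    out / "exclusion_report.json",
)
print(f"{len(report.kept)} subjects survive QC; report in {out}")
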