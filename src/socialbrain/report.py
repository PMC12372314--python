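"""Human-readable run summary: a demographics/QC table with group tests,
one line per preregistered analysis, and optional figures (group mean
network timecourses, metric boxplots)."""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import DataError
from .inference import BatteryResult, welch_t
from .prep import network_average

DEMOGRAPHIC_ROWS = ("age", "fsiq", "aq", "masc", "eq", "mean_fd", "n_censored")


def _fmt(x: float, nd: int = 3) -> str:
    return "nan" if not np.isfinite(x) else f"{x:.{nd}f}"


def demographics_table(cohort: pd.DataFrame, metrics: pd.DataFrame) -> pd.DataFrame:
    """Group mean (sd) and Welch test per demographic/QC variable."""
    joined = cohort.join(metrics[["mean_fd", "n_censored"]], how="inner")
    groups = sorted(joined["group"].unique())
    if len(groups) < 2:
        raise DataError("demographics table needs two groups")
    rows = []
    for var in DEMOGRAPHIC_ROWS:
        if var not in joined.columns:
            continue
        cells = {"variable": var}
        samples = []
        for g in groups:
            x = joined.loc[joined["group"] == g, var].dropna().astype(float)
            samples.append(x.to_numpy())
            cells[f"{g}_mean_sd"] = f"{_fmt(x.mean(), 2)} ({_fmt(x.std(ddof=1), 2)})"
            cells[f"{g}_n"] = len(x)
        res = welch_t(samples[0], samples[1])
        cells.update(t=res.t, p=res.p, d=res.d)
        rows.append(cells)
    return pd.DataFrame(rows)


def make_report(
    battery: BatteryResult,
    manifest,
    metrics: pd.DataFrame,
    cohort: pd.DataFrame,
) -> str:
    counts = cohort["group"].value_counts()
    if (counts < 1).any() or len(counts) < 2:
        raise DataError(
            f"report needs both groups represented, got {counts.to_dict()}"
        )
    lines = []
    lines.append("Social brain network analysis - run report")
    lines.append(f"config {manifest.config_hash[:12]}  seed {manifest.seed}")
    lines.append("")
    lines.append("Subject counts through QC gates:")
    for gate, n in manifest.subject_counts.items():
        lines.append(f"  {gate:>16s}: {n}")
    lines.append("")
    lines.append("Demographics / QC (group mean (sd), Welch t):")
    demo = demographics_table(cohort, metrics)
    lines.append(demo.to_string(index=False))
    lines.append("")
    lines.append("Inter-region correlation rows: within-ToM (15 pairs), "
                 "within-Pain (21 pairs), across (42 pairs)")
    for col in ("within_tom_z", "within_pain_z", "across_z"):
        by = metrics.join(cohort[["group"]])[["group", col]].groupby("group")[col]
        desc = ", ".join(
            f"{g}: m={_fmt(v.mean(), 3)} sd={_fmt(v.std(ddof=1), 3)}"
            for g, v in by
        )
        lines.append(f"  {col:>16s}  {desc}")
    lines.append("")
    lines.append("Hypothesis battery (group / focal terms):")
    for name, res in battery.models.items():
        focal = [t for t in res.terms.index if t not in ("const",)]
        inter = [t for t in focal if ":" in t]
        if inter:
            key = inter[-1]
        elif "group" in focal:
            key = "group"
        else:
            key = focal[-1]
        row = res.terms.loc[key]
        lines.append(
            f"  {name:>22s}  {key}: beta={_fmt(row['beta'])} "
            f"se={_fmt(row['se'])} t={_fmt(row['t'], 2)} p={_fmt(row['p'], 4)} "
            f"d={_fmt(row['d'], 2)} (n={res.n}"
            + (f", pruned {res.pruned}" if res.pruned else "")
            + ")"
        )
    lines.append("")
    lines.append("Heterogeneity t-tests:")
    for name, res in battery.ttests.items():
        lines.append(
            f"  {name:>22s}  diff={_fmt(res.mean_diff)} t({_fmt(res.df, 1)})="
            f"{_fmt(res.t, 2)} p={_fmt(res.p, 4)} d={_fmt(res.d, 2)}"
        )
    if battery.bayes:
        lines.append("")
        lines.append("Null-evidence Bayes factors (BIC approximation):")
        for name, bf in battery.bayes.items():
            lines.append(f"  {name:>22s}  BF01={_fmt(bf, 2)}")
    lines.append("")
    lines.append(
        f"Bonferroni-adjusted alpha for the MASC/AQ pair: "
        f"{battery.bonferroni_alpha:.3f}"
    )
    return "\n".join(lines) + "\n"


def make_plots(prepped: dict, groups: pd.Series, metrics: pd.DataFrame,
               out_dir: str | Path) -> list[Path]:
    """Group-mean network timecourse plots and metric boxplots (PNG)."""
    from matplotlib.figure import Figure

    out = Path(out_dir)
    written: list[Path] = []
    subjects = list(prepped)
    nets = prepped[subjects[0]].networks

    fig = Figure(figsize=(10, 6))
    for i, net in enumerate(nets):
        ax = fig.add_subplot(len(nets), 1, i + 1)
        for g in sorted(groups.unique()):
            sel = [s for s in subjects if groups[s] == g]
            mean_tc = np.mean(
                [network_average(prepped[s], net).values for s in sel], axis=0
            )
            ax.plot(mean_tc, label=g, lw=0.8)
        ax.set_title(f"{net} network group-average timecourse")
        ax.legend(loc="upper right", fontsize=8)
    path = out / "group_timecourses.png"
    fig.savefig(path, dpi=100)
    written.append(path)

    cols = [c for c in metrics.columns if c.endswith("_z")]
    fig = Figure(figsize=(2.2 * len(cols), 4))
    for i, col in enumerate(cols):
        ax = fig.add_subplot(1, len(cols), i + 1)
        data = [
            metrics.loc[[s for s in subjects if groups[s] == g], col].dropna()
            for g in sorted(groups.unique())
        ]
        ax.boxplot(data, tick_labels=sorted(groups.unique()))
        ax.set_title(col, fontsize=8)
    path = out / "metric_boxplots.png"
    fig.savefig(path, dpi=100)
    written.append(path)
    return written
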