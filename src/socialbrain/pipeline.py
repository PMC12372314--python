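"""End-to-end orchestration.

synthetic-or-load -> motion QC -> subject exclusion -> group matching ->
temporal prep -> network metrics -> hypothesis battery -> report.

All randomness flows from the single run seed; rerunning an identical
configuration reproduces every output file bit for bit.  The manifest
records the configuration hash, per-stage subject counts (monotonically
non-increasing through the QC gates) and output checksums.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io
from .config import RunConfig, config_hash, config_to_dict
from .containers import CensorMask, RoiTimecourseSet
from .errors import AnalysisError, DataError
from .inference import run_hypothesis_battery
from .metrics import (
    event_magnitude,
    group_similarity_summary,
    irc_summary,
    similarity_to_reference,
)
from .motion import compute_fd_filt4, detect_artifacts, exclude_subjects, match_groups_on_motion
from .prep import network_average, prep_pipeline
from .synthetic import simulate_cohort

__version__ = "0.1.0"


@dataclass
class RunManifest:
    config_hash: str
    version: str
    seed: int
    subject_counts: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    excluded: list[str] = field(default_factory=list)
    matched_removed: list[str] = field(default_factory=list)
    site_thresholds: dict[str, float] = field(default_factory=dict)

    def validate_gates(self) -> None:
        counts = list(self.subject_counts.values())
        if any(b > a for a, b in zip(counts, counts[1:])):
            raise AnalysisError("subject counts increased across a QC gate")


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except Exception as exc:  # noqa: BLE001 - tag the failing stage
        raise AnalysisError(f"[{name}] {exc}") from exc


def _load_real(config: RunConfig):
    atlas = io.read_atlas(config.atlas_map)
    cohort = pd.read_csv(config.cohort_csv).set_index("subject_id")
    tr = config.sim.tr_seconds
    timecourses, motion = {}, {}
    for sid in cohort.index:
        timecourses[sid] = io.read_timecourses(
            Path(config.timecourse_dir) / f"{sid}_timecourses.tsv", atlas, tr
        )
        motion[sid] = io.read_motion(Path(config.motion_dir) / f"{sid}_motion.tsv", tr)
    events = io.read_events(config.event_table) if config.event_table else []
    return cohort, timecourses, motion, events


def compute_metrics_table(
    prepped: dict[str, RoiTimecourseSet],
    groups: pd.Series,
    reference_group: str,
    event_window: tuple[int, int] | None,
    min_points: int = 10,
) -> pd.DataFrame:
    """Per-subject dependent-variable table over the kept subjects."""
    subjects = list(prepped)
    nets = prepped[subjects[0]].networks
    key_of = {n: n.lower() for n in nets}

    rows = {sid: {} for sid in subjects}
    for sid in subjects:
        s = irc_summary(prepped[sid], min_points=min_points)
        rows[sid].update(vars(s))

    for net in nets:
        key = key_of[net]
        net_tcs = [network_average(prepped[sid], net) for sid in subjects]
        ref_idx = [i for i, sid in enumerate(subjects) if groups[sid] == reference_group]
        if not ref_idx:
            raise DataError(f"no subjects in reference group {reference_group!r}")
        refs = [net_tcs[i] for i in ref_idx]
        for i, sid in enumerate(subjects):
            in_ref = groups[sid] == reference_group
            z = similarity_to_reference(
                net_tcs[i],
                refs,
                leave_self_out=in_ref,
                subject_index=ref_idx.index(i) if in_ref else None,
                min_points=min_points,
            )
            rows[sid][f"sim_nt_{key}_z"] = z
        sim = group_similarity_summary(
            net_tcs, [groups[sid] for sid in subjects], min_points=min_points
        )
        for i, sid in enumerate(subjects):
            rows[sid][f"within_group_{key}_z"] = sim.loc[i, "within_group_z"]
            rows[sid][f"across_group_{key}_z"] = sim.loc[i, "across_group_z"]

        if net == "ToM" and event_window is not None:
            for i, sid in enumerate(subjects):
                rows[sid]["t04_magnitude"] = event_magnitude(net_tcs[i], event_window)

    table = pd.DataFrame(rows).T
    table.index.name = "subject_id"
    return table


def run_pipeline(config: RunConfig) -> RunManifest:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- stage 1: synthetic generation or data loading -------------------
    if config.mode == "synthetic":
        sim = _stage("simulate", simulate_cohort, config.sim)
        cohort, timecourses, motion = sim.cohort, sim.timecourses, sim.motion
        events = sim.templates.event_table
        (out / "timecourses").mkdir(exist_ok=True)
        (out / "motion").mkdir(exist_ok=True)
        for sid in cohort.index:
            io.write_timecourses(timecourses[sid], out / "timecourses" / f"{sid}_timecourses.tsv")
            io.write_motion(motion[sid], out / "motion" / f"{sid}_motion.tsv")
        io.write_events(events, out / "events.tsv")
        io.write_atlas(config.sim.roi_networks, out / "atlas.tsv")
        io.write_json(sim.ground_truth, out / "ground_truth.json")
    else:
        cohort, timecourses, motion, events = _stage("load", _load_real, config)

    cohort.to_csv(out / "cohort.csv")
    manifest = RunManifest(
        config_hash=config_hash(config), version=__version__, seed=config.seed
    )
    manifest.subject_counts["initial"] = len(cohort)

    # --- stage 2: motion QC ---------------------------------------------
    ms = config.motion
    fd_by, mask_by = {}, {}
    for sid in cohort.index:
        fd = _stage(
            "motion_qc",
            compute_fd_filt4,
            motion[sid],
            band_hz=tuple(ms.band_hz),
            radius_mm=ms.radius_mm,
            bypass_filter=ms.bypass_filter,
            diff_mode=ms.diff_mode,
        )
        fd_by[sid] = fd
        mask_by[sid] = detect_artifacts(fd, threshold_mm=ms.threshold_mm, pad=ms.pad)
    (out / "fd").mkdir(exist_ok=True)
    for sid in cohort.index:
        io.write_fd(fd_by[sid], out / "fd" / f"{sid}_fd.tsv")
        io.write_mask(mask_by[sid], out / "fd" / f"{sid}_mask.tsv")

    report = _stage(
        "exclusions",
        exclude_subjects,
        fd_by,
        mask_by,
        dict(cohort["site"]),
        ms.fixed_thresholds,
    )
    kept = report.kept
    manifest.subject_counts["after_exclusion"] = len(kept)
    if not kept:
        raise AnalysisError("[exclusions] no subjects left after motion exclusion")

    # --- stage 3: group matching on motion ------------------------------
    qc = pd.DataFrame(
        {
            "mean_fd": {s: fd_by[s].mean_fd for s in kept},
            "n_censored": {s: float(mask_by[s].n_censored) for s in kept},
        }
    )
    removed = _stage(
        "matching",
        match_groups_on_motion,
        qc,
        cohort.loc[kept, "group"],
        alpha=ms.match_alpha,
        metric_names=tuple(ms.match_metrics),
    )
    report.flags.loc[removed, "matched_removed"] = True
    kept = [s for s in kept if s not in removed]
    manifest.subject_counts["after_matching"] = len(kept)
    manifest.excluded = report.excluded
    manifest.matched_removed = removed
    manifest.site_thresholds = report.site_thresholds
    io.write_json(
        {
            "flags": {
                s: {c: bool(v) for c, v in row.items()}
                for s, row in report.flags.iterrows()
            },
            "site_thresholds": report.site_thresholds,
        },
        out / "exclusion_report.json",
    )

    # --- stage 4: temporal prep -----------------------------------------
    prepped: dict[str, RoiTimecourseSet] = {}
    for sid in kept:
        tc = timecourses[sid]
        tc = RoiTimecourseSet(
            values=tc.values,
            roi_labels=tc.roi_labels,
            network_of=dict(tc.network_of),
            tr_seconds=tc.tr_seconds,
            censor=CensorMask(mask_by[sid].censored.copy()),
        )
        prepped[sid] = _stage(
            "prep",
            prep_pipeline,
            tc,
            cutoff_s=config.prep.highpass_cutoff_s,
            order=config.prep.filter_order,
        )

    # --- stage 5: metrics ------------------------------------------------
    window = None
    for label, start, end in events:
        if label == config.metrics.event_label:
            window = (start, end)
    metrics = _stage(
        "metrics",
        compute_metrics_table,
        prepped,
        cohort["group"],
        config.metrics.reference_group,
        window,
        config.metrics.min_joint_timepoints,
    )
    metrics["mean_fd"] = [fd_by[s].mean_fd for s in metrics.index]
    metrics["n_censored"] = [mask_by[s].n_censored for s in metrics.index]
    metrics.to_csv(out / "metrics.tsv", sep="\t")
    manifest.subject_counts["in_metrics"] = len(metrics)

    # --- stage 6: hypothesis battery ------------------------------------
    data = metrics.join(cohort, how="inner")
    battery = _stage(
        "battery",
        run_hypothesis_battery,
        data,
        prune_alpha=config.battery.prune_alpha,
        standardize=config.battery.standardize,
        null_evidence_models=tuple(config.battery.null_evidence_models),
    )
    battery.to_frame().to_csv(out / "battery.tsv", sep="\t", index=False)
    io.write_json(
        {
            "models": {
                name: {
                    "terms": res.terms.to_dict(orient="index"),
                    "n": res.n,
                    "pruned": res.pruned,
                    "bic": res.bic,
                    "r_squared": res.r_squared,
                }
                for name, res in battery.models.items()
            },
            "ttests": {name: vars(res) for name, res in battery.ttests.items()},
            "bayes_bf01": battery.bayes,
            "bonferroni_alpha": battery.bonferroni_alpha,
            "bonferroni_adjusted": battery.bonferroni_adjusted,
        },
        out / "battery.json",
    )

    # --- stage 7: report and manifest -----------------------------------
    from .report import make_report, make_plots

    text = _stage("report", make_report, battery, manifest, metrics, cohort.loc[kept])
    (out / "report.txt").write_text(text)
    if config.make_plots:
        _stage("plots", make_plots, prepped, cohort.loc[kept, "group"], metrics, out)

    manifest.validate_gates()
    for f in sorted(out.rglob("*")):
        if f.is_file() and f.name != "manifest.json":
            manifest.checksums[str(f.relative_to(out))] = io.file_sha256(f)
    io.write_json(
        {"config": config_to_dict(config), **dataclasses.asdict(manifest)},
        out / "manifest.json",
    )
    return manifest
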