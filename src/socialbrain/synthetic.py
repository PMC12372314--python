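"""Synthetic movie-watching cohort generator.

The generator emulates the statistical structure the downstream analyses
assume, so every stage is testable without scanner data:

* two evoked network templates (ToM, Pain) plus one shared audiovisual
  component, built from Gaussian-smoothed white noise and mutually
  orthogonalized — they stand in for the film, not for any actual scene;
* per subject, each ROI of network N follows the factor model

      y_r(t) = c_{g,N} f_N(t) + lam f_{N'}(t) + a s(t)
               + idio_sd * u_subj(t) + noise_sd * eps_r(t)

  with one idiosyncratic series ``u_subj`` shared across the subject's
  ROIs (idiosyncratic but internally coherent responses) and the leak
  coefficient lam = cross_network_leak * c_{g,N'};
* a six-parameter motion trace (smooth random walk + pseudo-respiratory
  sinusoid + Poisson-placed displacement spikes); the spike TRs also
  receive additive artifacts in the BOLD series so censoring has
  consequences;
* behavioral scores with group mean shifts and an optional coupling of a
  score to a neural metric within one group.

All randomness flows from integer seeds through independent
``numpy.random.SeedSequence`` substreams, so identical configuration
yields bit-identical cohorts.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import SimConfig
from .containers import (
    CensorMask,
    EvokedTemplates,
    MotionTrace,
    RoiTimecourseSet,
)
from .errors import ConfigError, DataError

_MAX_TEMPLATE_REDRAWS = 5
_FWHM_TO_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))

# substream keys: one per independent random draw family
_STREAM_TEMPLATES = 0
_STREAM_TIMECOURSE = 1
_STREAM_MOTION = 2
_STREAM_ARTIFACTS = 3
_STREAM_BEHAVIOR = 4


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def subject_seed(global_seed: int, subject_index: int) -> int:
    """Stable per-subject seed, independent of the rest of the subject set."""
    ss = np.random.SeedSequence(entropy=global_seed, spawn_key=(1000 + subject_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def _standardize(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd < 1e-12:
        raise DataError("degenerate (zero-variance) series")
    return (x - x.mean()) / sd


def _smooth_noise(rng: np.random.Generator, n: int, sigma_samples: float) -> np.ndarray:
    x = rng.standard_normal(n)
    if sigma_samples > 0:
        x = gaussian_filter1d(x, sigma_samples, mode="wrap")
    return x


def _orthogonalize(x: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Residual of x after projecting out already-standardized basis series."""
    x = x - x.mean()
    for b in basis:
        x = x - (x @ b) / (b @ b) * b
    return x


def generate_templates(config: SimConfig) -> EvokedTemplates:
    """Build the shared evoked structure of the movie stimulus.

    Each template is smoothed white noise (FWHM ``template_smooth_s``),
    orthogonalized against the previously built components and standardized
    to zero mean / unit variance, so the two network templates correlate at
    exactly zero (well inside the configured bound).  The event table places
    the final mental-state event at the ToM template's largest excursion and
    a pain event at the Pain template's peak, both 3 TRs wide.
    """
    n = config.n_timepoints
    sigma = config.template_smooth_s / _FWHM_TO_SIGMA / config.tr_seconds
    rng = _rng(config.seed, _STREAM_TEMPLATES)
    net_a, net_b = config.network_labels

    for _ in range(_MAX_TEMPLATE_REDRAWS):
        shared = _smooth_noise(rng, n, sigma)
        f_a = _smooth_noise(rng, n, sigma)
        f_b = _smooth_noise(rng, n, sigma)
        try:
            shared = _standardize(shared - shared.mean())
            f_a = _standardize(_orthogonalize(f_a, [shared]))
            f_b = _standardize(_orthogonalize(f_b, [shared, f_a]))
        except DataError:
            continue
        evoked = {net_a: f_a, net_b: f_b}
        r = float(np.corrcoef(f_a, f_b)[0, 1])
        if abs(r) < config.template_corr_bound:
            break
    else:
        raise ConfigError(
            "could not draw near-orthogonal templates; degenerate configuration"
        )

    def _window(series: np.ndarray, width: int = 3) -> tuple[int, int]:
        peak = int(np.argmax(series))
        start = max(0, min(peak - width // 2, n - width))
        return start, start + width

    tom_net = net_a if net_a == "ToM" else (net_b if net_b == "ToM" else net_a)
    pain_net = net_b if tom_net == net_a else net_a
    events = [
        ("T04", *_window(evoked[tom_net])),
        ("P01", *_window(evoked[pain_net])),
    ]
    return EvokedTemplates(
        evoked=evoked, shared=shared, event_table=events, tr_seconds=config.tr_seconds
    )


def generate_subject_timecourses(
    config: SimConfig,
    templates: EvokedTemplates,
    subject_group: str,
    subject_seed: int,
    artifact_indices: np.ndarray | None = None,
) -> RoiTimecourseSet:
    """Simulate one subject's T x R ROI series under the factor model.

    The idiosyncratic series is smoothed like the templates, orthogonalized
    against them (idiosyncratic = unshared by construction) and
    standardized.  When ``artifact_indices`` is given, a constant spike of
    ``artifact_bold_amp`` (z units) is added to every ROI at those TRs —
    the BOLD footprint of the motion spikes, shared across regions.
    Identical seeds give identical outputs; artifact injection draws no
    randomness, so spiked and clean versions of a subject share components.
    """
    groups = set(g for g, _ in config.loading_by_group_network)
    if subject_group not in groups:
        raise ConfigError(f"unknown group label: {subject_group!r}")
    n = config.n_timepoints
    sigma = config.template_smooth_s / _FWHM_TO_SIGMA / config.tr_seconds
    rng = _rng(subject_seed, _STREAM_TIMECOURSE)

    nets = config.network_labels
    basis = [templates.shared] + [templates.evoked[m] for m in nets]
    u = _standardize(_orthogonalize(_smooth_noise(rng, n, sigma), basis))

    rois = list(config.roi_networks)
    eps = rng.standard_normal((n, len(rois)))

    values = np.empty((n, len(rois)))
    for j, roi in enumerate(rois):
        net = config.roi_networks[roi]
        other = nets[0] if net == nets[1] else nets[1]
        c = config.loading_by_group_network[(subject_group, net)]
        lam = config.cross_network_leak * config.loading_by_group_network[
            (subject_group, other)
        ]
        values[:, j] = (
            c * templates.evoked[net]
            + lam * templates.evoked[other]
            + config.shared_loading * templates.shared
            + config.idio_sd * u
            + config.noise_sd * eps[:, j]
        )
    if artifact_indices is not None and len(artifact_indices):
        values[np.asarray(artifact_indices, dtype=int), :] += config.artifact_bold_amp

    return RoiTimecourseSet(
        values=values,
        roi_labels=rois,
        network_of=dict(config.roi_networks),
        tr_seconds=config.tr_seconds,
        censor=CensorMask.none(n),
    )


def draw_artifact_indices(config: SimConfig, subject_seed: int) -> np.ndarray:
    """Poisson-style spike placement: each TR in [4, T) spikes independently
    with probability ``artifact_rate`` (expected count ~ rate * T)."""
    rng = _rng(subject_seed, _STREAM_ARTIFACTS)
    hits = rng.random(config.n_timepoints) < config.artifact_rate
    hits[:4] = False  # lag-4 differencing has no history before TR 4
    return np.flatnonzero(hits)


def generate_motion(config: SimConfig, subject_seed: int) -> MotionTrace:
    """Simulate a six-parameter realignment trace.

    Smooth random walk + pseudo-respiratory sinusoid (default 0.33 Hz, the
    band the FD filter is meant to remove) + displacement spikes of
    ``artifact_fd_mm`` at the ground-truth artifact TRs (recorded on the
    returned trace).  Rotation columns use the same model scaled to radians
    on a 50 mm sphere so their arc displacement matches the translations.
    """
    n = config.n_timepoints
    tr = config.tr_seconds
    rng = _rng(subject_seed, _STREAM_MOTION)
    t = np.arange(n) * tr

    values = np.zeros((n, 6))
    for col in range(6):
        scale = config.walk_step_mm if col < 3 else config.walk_step_mm / 50.0
        ramp = config.resp_amp_mm if col < 3 else config.resp_amp_mm / 50.0
        walk = np.cumsum(rng.normal(0.0, scale, n)) if scale > 0 else np.zeros(n)
        if scale > 0:
            walk = gaussian_filter1d(walk, 3.0, mode="nearest")
        phase = rng.uniform(0, 2 * np.pi)
        resp = ramp * np.sin(2 * np.pi * config.resp_hz * t + phase) if ramp > 0 else 0.0
        values[:, col] = walk + resp

    artifacts = draw_artifact_indices(config, subject_seed)
    values[artifacts, 0] += config.artifact_fd_mm

    return MotionTrace(values=values, tr_seconds=tr, artifact_indices=artifacts)


def generate_cohort_frame(config: SimConfig) -> pd.DataFrame:
    """Subject ids, group labels and (alternating) site assignments."""
    rows = []
    idx = 0
    for group, n in config.n_per_group.items():
        for i in range(n):
            rows.append(
                {
                    "subject_id": f"sub-{group}-{i + 1:03d}",
                    "group": group,
                    "site": config.sites[i % len(config.sites)],
                    "subject_index": idx,
                }
            )
            idx += 1
    return pd.DataFrame(rows).set_index("subject_id")


def generate_behavior(
    config: SimConfig,
    cohort: pd.DataFrame,
    neural_metrics: pd.DataFrame,
) -> pd.DataFrame:
    """Fill demographic and behavioral columns of the cohort table.

    Scores follow the configured per-group normal distributions; a coupled
    score additionally tracks the standardized neural metric within the
    coupled group at correlation ``rho`` (noise mixed in at sqrt(1-rho^2)),
    leaving its marginal mean/sd at the configured values.
    """
    for score, coupling in config.behavior_coupling.items():
        if coupling.metric not in neural_metrics.columns:
            raise ConfigError(
                f"behavior coupling for {score} references unknown metric "
                f"{coupling.metric!r}"
            )
    missing = [s for s in cohort.index if s not in neural_metrics.index]
    if missing:
        raise DataError(f"neural metrics missing for subjects: {missing[:5]}")

    rng = _rng(config.seed, _STREAM_BEHAVIOR)
    out = cohort.copy()
    n = len(out)
    groups = out["group"].to_numpy()

    out["age"] = np.clip(rng.normal(*config.age_mean_sd, n), 18, None)
    out["fsiq"] = rng.normal(*config.fsiq_mean_sd, n)
    female_p = np.array([config.female_frac.get(g, 0.5) for g in groups])
    out["sex"] = np.where(rng.random(n) < female_p, "F", "M")
    out["handedness"] = np.where(rng.random(n) < 0.9, "R", "L")

    metric_values = neural_metrics.reindex(out.index)
    for score, dist_by_group in config.score_distributions.items():
        coupling = config.behavior_coupling.get(score)
        noise = rng.standard_normal(n)
        values = np.empty(n)
        for g in np.unique(groups):
            sel = groups == g
            mu, sd = dist_by_group[g]
            if coupling is not None and (coupling.group is None or coupling.group == g):
                m = metric_values.loc[sel, coupling.metric].to_numpy(dtype=float)
                m_sd = m.std()
                z = (m - m.mean()) / m_sd if m_sd > 1e-12 else np.zeros(sel.sum())
                mix = coupling.rho * z + np.sqrt(1 - coupling.rho**2) * noise[sel]
            else:
                mix = noise[sel]
            values[sel] = mu + sd * mix
        out[score.lower()] = values
    return out


@dataclass
class SimulatedCohort:
    """Everything the generator knows about one synthetic cohort."""

    config: SimConfig
    templates: EvokedTemplates
    cohort: pd.DataFrame
    timecourses: dict[str, RoiTimecourseSet]
    clean_timecourses: dict[str, RoiTimecourseSet]
    motion: dict[str, MotionTrace]
    ground_truth: dict = field(default_factory=dict)


def simulate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate a full cohort: templates, per-subject series + motion,
    behavior coupled to the subjects' artifact-free neural metrics."""
    from .metrics import irc_summary  # deferred: metrics does not import us

    templates = generate_templates(config)
    frame = generate_cohort_frame(config)

    timecourses: dict[str, RoiTimecourseSet] = {}
    clean: dict[str, RoiTimecourseSet] = {}
    motion: dict[str, MotionTrace] = {}
    seeds: dict[str, int] = {}
    artifacts: dict[str, list[int]] = {}

    for sid, row in frame.iterrows():
        s = subject_seed(config.seed, int(row["subject_index"]))
        seeds[sid] = s
        trace = generate_motion(config, s)
        motion[sid] = trace
        artifacts[sid] = [int(i) for i in trace.artifact_indices]
        clean[sid] = generate_subject_timecourses(config, templates, row["group"], s)
        timecourses[sid] = generate_subject_timecourses(
            config, templates, row["group"], s, artifact_indices=trace.artifact_indices
        )

    neural = pd.DataFrame(
        {
            sid: vars(irc_summary(tc))
            for sid, tc in clean.items()
        }
    ).T
    cohort = generate_behavior(config, frame, neural)

    ground_truth = {
        "seed": config.seed,
        "subject_seeds": seeds,
        "artifact_indices": artifacts,
        "loadings": {f"{g}|{n}": v for (g, n), v in config.loading_by_group_network.items()},
        "event_table": [list(e) for e in templates.event_table],
    }
    return SimulatedCohort(
        config=config,
        templates=templates,
        cohort=cohort,
        timecourses=timecourses,
        clean_timecourses=clean,
        motion=motion,
        ground_truth=ground_truth,
    )
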