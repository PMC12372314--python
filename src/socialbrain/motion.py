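"""Head-motion quality control.

Filtered framewise displacement (FDfilt4), artifact-timepoint detection
with padding, per-site subject exclusion, and iterative group matching on
motion metrics.

FDfilt4 at TR t is the sum over the six realignment parameters of the
absolute lag-4 backward differences |p[t] - p[t-4]|, computed after
band-stop filtering each parameter to remove pseudo-respiratory frequencies
(a convention from the multiband motion literature, where respiration
aliases into the realignment estimates).  Rotations are converted to arc
displacement on a 50 mm sphere before differencing.  The first four FD
entries are defined as 0 so the mean is taken over all TRs.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal, stats

from .containers import CensorMask, ExclusionReport, FDSeries, MotionTrace
from .errors import AnalysisError, ConfigError, DataError

FD_LAG = 4


def _bandstop(values: np.ndarray, tr_seconds: float, band_hz: tuple[float, float],
              order: int = 10) -> np.ndarray:
    low, high = band_hz
    nyquist = 0.5 / tr_seconds
    if not (0 < low < high < nyquist):
        raise ConfigError(
            f"band {band_hz} must satisfy 0 < low < high < Nyquist ({nyquist:.3f} Hz)"
        )
    sos = signal.butter(order, [low, high], btype="bandstop", fs=1.0 / tr_seconds,
                        output="sos")
    padlen = 3 * (2 * sos.shape[0] + 1)
    if values.shape[0] <= padlen:
        raise DataError(
            f"trace too short ({values.shape[0]} TRs) for the band-stop filter; "
            f"need more than {padlen} or bypass_filter=True"
        )
    return signal.sosfiltfilt(sos, values, axis=0)


def compute_fd_filt4(
    trace: MotionTrace,
    band_hz: tuple[float, float] = (0.31, 0.43),
    radius_mm: float = 50.0,
    bypass_filter: bool = False,
    diff_mode: str = "lag4",
) -> FDSeries:
    """Compute FDfilt4 (mm) from a realignment trace.

    ``diff_mode`` selects the reading of "backward differences over four
    timepoints": ``"lag4"`` (default) uses p[t] - p[t-4]; ``"sum4"`` sums
    the four successive lag-1 absolute differences over the same window.
    """
    params = trace.values.copy()
    if not bypass_filter:
        params = _bandstop(params, trace.tr_seconds, band_hz)
    params[:, 3:] *= radius_mm  # rotations (rad) -> arc displacement (mm)

    n = params.shape[0]
    fd = np.zeros(n)
    if diff_mode == "lag4":
        diffs = np.abs(params[FD_LAG:] - params[:-FD_LAG])
        fd[FD_LAG:] = diffs.sum(axis=1)
    elif diff_mode == "sum4":
        step = np.abs(np.diff(params, axis=0)).sum(axis=1)
        for t in range(FD_LAG, n):
            fd[t] = step[t - FD_LAG:t].sum()
    else:
        raise ConfigError(f"unknown diff_mode {diff_mode!r}")
    return FDSeries(fd_mm=fd)


def detect_artifacts(
    fd: FDSeries | np.ndarray, threshold_mm: float = 0.5, pad: int = 2
) -> CensorMask:
    """Mark TRs with FD above threshold, plus ``pad`` TRs on either side."""
    if threshold_mm <= 0:
        raise ConfigError("threshold_mm must be positive")
    if pad < 0:
        raise ConfigError("pad must be >= 0")
    values = fd.fd_mm if isinstance(fd, FDSeries) else np.asarray(fd, dtype=float)
    n = values.shape[0]
    mask = np.zeros(n, dtype=bool)
    for i in np.flatnonzero(values > threshold_mm):
        mask[max(0, i - pad): min(n, i + pad + 1)] = True
    return CensorMask(mask)


def iqr_threshold(values: np.ndarray) -> float:
    """Median + 1.5 * IQR of the supplied sample."""
    q25, q75 = np.percentile(values, [25, 75])
    return float(np.median(values) + 1.5 * (q75 - q25))


def exclude_subjects(
    fd_by_subject: dict[str, FDSeries],
    mask_by_subject: dict[str, CensorMask],
    site_by_subject: dict[str, str],
    fixed_thresholds: dict[str, float] | None = None,
) -> ExclusionReport:
    """Flag subjects for exclusion on motion grounds.

    ``iqr_outlier``: mean FD above the per-site median + 1.5 IQR threshold.
    Thresholds come from ``fixed_thresholds`` when supplied (e.g. values
    derived from a larger project sample); otherwise they are computed on
    the input sample, which requires at least two subjects per site.
    ``over_one_third``: more than a third of the scan censored.
    ``matched_removed`` is initialized False; the matching step fills it.
    """
    subjects = list(fd_by_subject)
    for s in subjects:
        if s not in mask_by_subject or s not in site_by_subject:
            raise DataError(f"subject {s} missing a censor mask or site label")

    mean_fd = {s: fd_by_subject[s].mean_fd for s in subjects}
    thresholds: dict[str, float] = {}
    for site in sorted(set(site_by_subject[s] for s in subjects)):
        if fixed_thresholds is not None and site in fixed_thresholds:
            thresholds[site] = float(fixed_thresholds[site])
            continue
        values = np.array([mean_fd[s] for s in subjects if site_by_subject[s] == site])
        if values.size < 2:
            raise DataError(
                f"site {site!r} has a single subject and no fixed threshold; "
                "cannot estimate an IQR threshold"
            )
        thresholds[site] = iqr_threshold(values)

    flags = pd.DataFrame(
        {
            "iqr_outlier": [
                mean_fd[s] > thresholds[site_by_subject[s]] for s in subjects
            ],
            "over_one_third": [
                mask_by_subject[s].frac_censored > 1.0 / 3.0 for s in subjects
            ],
            "matched_removed": False,
        },
        index=pd.Index(subjects, name="subject_id"),
    )
    return ExclusionReport(flags=flags, site_thresholds=thresholds)


def _safe_ttest(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample t-test p-value, defined even for degenerate variances.

    Groups whose values are identical up to floating-point residue are
    treated as constant (scipy's Welch t on ~1e-17 variances is garbage).
    """
    scale = max(np.abs(a).max(), np.abs(b).max(), 1e-30)
    if a.std(ddof=1) < 1e-12 * scale and b.std(ddof=1) < 1e-12 * scale:
        return 1.0 if abs(a.mean() - b.mean()) <= 1e-12 * scale else 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(p) if np.isfinite(p) else 1.0


def _min_p(metrics: pd.DataFrame, groups: pd.Series, metric_names) -> float:
    labels = groups.unique()
    g1 = metrics.loc[groups == labels[0]]
    g2 = metrics.loc[groups == labels[1]]
    return min(
        _safe_ttest(g1[m].to_numpy(dtype=float), g2[m].to_numpy(dtype=float))
        for m in metric_names
    )


def match_groups_on_motion(
    metrics: pd.DataFrame,
    groups: pd.Series,
    alpha: float = 0.05,
    metric_names: tuple[str, ...] = ("mean_fd", "n_censored"),
    min_group_size: int = 3,
) -> list[str]:
    """Iteratively remove extreme subjects until motion metrics match.

    While any listed metric differs between the two groups at p < alpha
    (two-sample t-test), one subject is removed per iteration: among the
    candidate extremes (the maximum of the higher-mean group and the
    minimum of the lower-mean group, for each unmatched metric) the one
    whose removal most increases the minimum p across metrics is chosen,
    ties broken by subject-identifier order.  Returns removed ids in order.
    """
    metrics = metrics.copy()
    groups = groups.loc[metrics.index]
    labels = list(pd.unique(groups))
    if len(labels) != 2:
        raise AnalysisError("matching requires exactly two groups")
    for g in labels:
        if (groups == g).sum() < min_group_size:
            raise AnalysisError(f"group {g!r} smaller than {min_group_size}")
    for m in metric_names:
        if m not in metrics.columns:
            raise DataError(f"metric column {m!r} missing")

    removed: list[str] = []
    while _min_p(metrics, groups, metric_names) < alpha:
        candidates: set[str] = set()
        for m in metric_names:
            means = {g: metrics.loc[groups == g, m].mean() for g in labels}
            hi = max(labels, key=lambda g: means[g])
            lo = min(labels, key=lambda g: means[g])
            candidates.add(metrics.loc[groups == hi, m].idxmax())
            candidates.add(metrics.loc[groups == lo, m].idxmin())
        best: tuple[float, str] | None = None
        for cand in sorted(candidates):
            sub = metrics.drop(index=cand)
            p = _min_p(sub, groups.drop(index=cand), metric_names)
            if best is None or p > best[0]:
                best = (p, cand)
        assert best is not None
        _, chosen = best
        metrics = metrics.drop(index=chosen)
        groups = groups.drop(index=chosen)
        removed.append(chosen)
        for g in labels:
            if (groups == g).sum() < min_group_size:
                raise AnalysisError(
                    f"matching failed: group {g!r} would fall below "
                    f"{min_group_size} subjects"
                )
    return removed
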