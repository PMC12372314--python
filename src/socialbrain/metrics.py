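"""Dependent variables of the analysis.

Inter-region correlation (IRC): within-subject Pearson correlations between
ROI timecourses, Fisher-transformed per pair and averaged over within-ToM
pairs (15 under the default atlas), within-Pain pairs (21) and ToM x Pain
pairs (42).  All summaries are means of Fisher z values, never the z of a
mean r.

Inter-subject correlation (ISC): correlation of network-average timecourses
across subjects — to a reference-group average (leave-one-out for members
of the reference group), and pairwise within/across groups.

Censoring convention: a subject's artifact TRs are excluded from every
correlation involving that subject; between-subject correlations exclude
the union of both subjects' censored TRs.  Any correlation needs at least
``min_points`` jointly valid timepoints.
"""
from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .containers import CensorMask, IRCSummary, NetworkTimecourse, RoiTimecourseSet
from .errors import DataError

R_CLIP = 1.0 - 1e-7
DEFAULT_MIN_POINTS = 10


def fisher_z(r: float) -> float:
    """arctanh with |r| clipped to 1 - 1e-7 so r = +-1 stays finite."""
    if not np.isfinite(r):
        raise DataError("correlation must be finite")
    if abs(r) > 1:
        raise DataError(f"|r| must be <= 1, got {r}")
    return float(np.arctanh(np.clip(r, -R_CLIP, R_CLIP)))


def pairwise_correlation(
    x: np.ndarray,
    y: np.ndarray,
    mask_x: CensorMask | None = None,
    mask_y: CensorMask | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
) -> float:
    """Pearson r over timepoints valid in both masks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("series must have equal length")
    valid = np.ones(x.shape[0], dtype=bool)
    if mask_x is not None:
        valid &= ~mask_x.censored
    if mask_y is not None:
        valid &= ~mask_y.censored
    if valid.sum() < min_points:
        raise DataError(
            f"only {int(valid.sum())} jointly valid timepoints "
            f"(need >= {min_points}); pair unusable"
        )
    return float(np.corrcoef(x[valid], y[valid])[0, 1])


def irc_summary(
    tc: RoiTimecourseSet, min_points: int = DEFAULT_MIN_POINTS
) -> IRCSummary:
    """Per-subject IRC summary over the subject's own uncensored TRs.

    All ROI pairs are correlated on the same (subject-level) valid TR set,
    Fisher-transformed per pair, then averaged within each network and
    across networks.
    """
    net_a, net_b = tc.networks
    tom = net_a if net_a == "ToM" else (net_b if net_b == "ToM" else net_a)
    pain = net_b if tom == net_a else net_a

    valid = ~tc.censor.censored
    if valid.sum() < min_points:
        raise DataError("too few uncensored timepoints for IRC")
    data = tc.values[valid]
    corr = np.corrcoef(data.T)

    idx = {r: j for j, r in enumerate(tc.roi_labels)}
    tom_rois = tc.rois_in(tom)
    pain_rois = tc.rois_in(pain)

    def mean_z(pairs) -> float:
        zs = [fisher_z(corr[idx[a], idx[b]]) for a, b in pairs]
        return float(np.mean(zs))

    return IRCSummary(
        within_tom_z=mean_z(itertools.combinations(tom_rois, 2)),
        within_pain_z=mean_z(itertools.combinations(pain_rois, 2)),
        across_z=mean_z(itertools.product(tom_rois, pain_rois)),
    )


def similarity_to_reference(
    subject: NetworkTimecourse,
    reference_group: list[NetworkTimecourse],
    leave_self_out: bool = False,
    subject_index: int | None = None,
    min_points: int = DEFAULT_MIN_POINTS,
) -> float:
    """Fisher z similarity of a subject to the reference-group average.

    The reference average at each timepoint is the mean over reference
    subjects with valid (uncensored) data there; timepoints with no valid
    reference subject are dropped.  With ``leave_self_out`` the subject at
    ``subject_index`` in the reference list is removed from the average
    (the leave-one-out convention for reference-group members; non-members
    are compared to the full-group average).
    """
    refs = list(reference_group)
    if leave_self_out:
        if subject_index is None:
            raise DataError("leave_self_out requires subject_index")
        if len(refs) < 2:
            raise DataError("leave-one-out needs at least 2 reference subjects")
        refs = refs[:subject_index] + refs[subject_index + 1:]
    if not refs:
        raise DataError("reference group is empty")

    stack = np.stack([r.values for r in refs])
    invalid = np.stack([r.censor.censored for r in refs])
    stack = np.where(invalid, np.nan, stack)
    counts = (~invalid).sum(axis=0)
    with np.errstate(invalid="ignore"):
        ref_mean = np.nanmean(stack, axis=0)

    valid = (counts > 0) & ~subject.censor.censored
    if valid.sum() < min_points:
        raise DataError("too few valid timepoints against the reference average")
    r = float(np.corrcoef(subject.values[valid], ref_mean[valid])[0, 1])
    return fisher_z(r)


def pairwise_z_matrix(
    tcs: list[NetworkTimecourse], min_points: int = DEFAULT_MIN_POINTS
) -> np.ndarray:
    """Symmetric matrix of pairwise Fisher z similarities (nan diagonal)."""
    n = len(tcs)
    z = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            r = pairwise_correlation(
                tcs[i].values,
                tcs[j].values,
                tcs[i].censor,
                tcs[j].censor,
                min_points=min_points,
            )
            z[i, j] = z[j, i] = fisher_z(r)
    return z


def group_similarity_summary(
    tcs: list[NetworkTimecourse],
    groups: list[str],
    min_points: int = DEFAULT_MIN_POINTS,
) -> pd.DataFrame:
    """Per-subject mean similarity to own-group and other-group subjects.

    Returns a DataFrame (one row per subject, in input order) with columns
    ``within_group_z`` (mean z to every other own-group subject) and
    ``across_group_z`` (mean z to all other-group subjects).
    """
    if len(tcs) != len(groups):
        raise DataError("one group label per timecourse required")
    labels = np.asarray(groups)
    for g in np.unique(labels):
        if (labels == g).sum() < 2:
            raise DataError(f"group {g!r} needs at least 2 subjects")
    z = pairwise_z_matrix(tcs, min_points=min_points)
    rows = []
    for i in range(len(tcs)):
        own = (labels == labels[i]) & (np.arange(len(tcs)) != i)
        other = labels != labels[i]
        rows.append(
            {
                "within_group_z": float(np.mean(z[i, own])),
                "across_group_z": float(np.mean(z[i, other])),
            }
        )
    return pd.DataFrame(rows)


def event_magnitude(
    tc: NetworkTimecourse, event_window: tuple[int, int]
) -> float:
    """Mean of the network series over uncensored TRs in [start, end).

    Returns nan when the whole window is censored (excluded listwise in
    the inference stage).
    """
    start, end = event_window
    n = tc.values.shape[0]
    if not (0 <= start < end <= n):
        raise DataError(f"event window {event_window} outside [0, {n})")
    sel = np.zeros(n, dtype=bool)
    sel[start:end] = True
    sel &= ~tc.censor.censored
    if not sel.any():
        return float("nan")
    return float(tc.values[sel].mean())
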