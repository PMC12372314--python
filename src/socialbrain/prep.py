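"""Temporal denoising of ROI timecourses.

Fixed pipeline order: interpolate censored artifacts -> zero-phase
Butterworth high-pass (100 s cutoff) -> z-score, with the censor mask
retained so correlational analyses can exclude artifact TRs afterwards.
Interpolation precedes filtering so spikes do not ring through the filter;
z-scoring uses all timepoints because censoring is applied subsequently,
in the analyses, not here.
"""
from __future__ import annotations

import numpy as np
from scipy import signal

from .containers import NetworkTimecourse, RoiTimecourseSet
from .errors import ConfigError, DataError


def interpolate_artifacts(tc: RoiTimecourseSet) -> RoiTimecourseSet:
    """Replace censored samples by linear interpolation between flanking
    uncensored samples; edge runs hold the nearest uncensored value."""
    censored = tc.censor.censored
    if not censored.any():
        return tc.with_values(tc.values.copy())
    good = np.flatnonzero(~censored)
    if good.size < 2:
        raise DataError("fewer than 2 uncensored timepoints; subject unusable")
    t = np.arange(tc.n_timepoints)
    out = tc.values.copy()
    for j in range(out.shape[1]):
        out[censored, j] = np.interp(t[censored], good, out[good, j])
    return tc.with_values(out)


def highpass(
    tc: RoiTimecourseSet, cutoff_s: float = 100.0, order: int = 5
) -> RoiTimecourseSet:
    """Zero-phase Butterworth high-pass at 1/cutoff_s Hz, per ROI."""
    if cutoff_s <= 2 * tc.tr_seconds:
        raise ConfigError(
            f"cutoff period {cutoff_s}s must exceed twice the sampling "
            f"interval ({2 * tc.tr_seconds}s)"
        )
    sos = signal.butter(
        order, 1.0 / cutoff_s, btype="highpass", fs=1.0 / tc.tr_seconds, output="sos"
    )
    padlen = 3 * (2 * sos.shape[0] + 1)
    if tc.n_timepoints <= padlen:
        raise DataError(f"series too short for filtering (need > {padlen} TRs)")
    return tc.with_values(signal.sosfiltfilt(sos, tc.values, axis=0))


def zscore(tc: RoiTimecourseSet) -> RoiTimecourseSet:
    """Standardize each ROI column to mean 0, sd 1 over all timepoints."""
    sd = tc.values.std(axis=0)
    if np.any(sd < 1e-12):
        bad = [tc.roi_labels[j] for j in np.flatnonzero(sd < 1e-12)]
        raise DataError(f"zero-variance ROI(s): {bad}")
    return tc.with_values((tc.values - tc.values.mean(axis=0)) / sd)


def prep_pipeline(
    tc: RoiTimecourseSet, cutoff_s: float = 100.0, order: int = 5
) -> RoiTimecourseSet:
    """interpolate -> highpass -> zscore (the fixed stage order)."""
    return zscore(highpass(interpolate_artifacts(tc), cutoff_s=cutoff_s, order=order))


def network_average(tc: RoiTimecourseSet, network: str) -> NetworkTimecourse:
    """Unweighted mean across the network's ROI columns; censor inherited."""
    rois = tc.rois_in(network)
    if not rois:
        raise DataError(f"unknown or empty network: {network!r}")
    cols = [tc.roi_labels.index(r) for r in rois]
    return NetworkTimecourse(
        values=tc.values[:, cols].mean(axis=1),
        network=network,
        censor=tc.censor,
    )
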