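"""In-memory containers shared across pipeline stages.

All arrays are plain numpy; tables are pandas.  Containers validate their
own invariants at construction so downstream code can assume them.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError

MOTION_COLUMNS = ("trans_x", "trans_y", "trans_z", "rot_x", "rot_y", "rot_z")


@dataclass
class CensorMask:
    """Boolean artifact mask over the scan; True = censored timepoint."""

    censored: np.ndarray

    def __post_init__(self) -> None:
        self.censored = np.asarray(self.censored, dtype=bool)
        if self.censored.ndim != 1:
            raise DataError("censor mask must be 1-D")

    @property
    def n_timepoints(self) -> int:
        return self.censored.shape[0]

    @property
    def n_censored(self) -> int:
        return int(self.censored.sum())

    @property
    def frac_censored(self) -> float:
        return self.n_censored / self.n_timepoints

    @classmethod
    def none(cls, n_timepoints: int) -> "CensorMask":
        return cls(np.zeros(n_timepoints, dtype=bool))


@dataclass
class MotionTrace:
    """T x 6 realignment parameters: translations in mm, rotations in radians.

    ``artifact_indices`` carries simulation ground truth (TRs where spikes
    were injected); it is None for real data.
    """

    values: np.ndarray
    tr_seconds: float
    artifact_indices: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 6:
            raise DataError("motion trace must be a T x 6 array")
        if self.values.shape[0] < 8:
            raise DataError("motion trace needs at least 8 timepoints (lag-4 history)")
        if not np.all(np.isfinite(self.values)):
            raise DataError("motion trace contains non-finite values")
        if self.tr_seconds <= 0:
            raise DataError("tr_seconds must be positive")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]


@dataclass
class FDSeries:
    """Filtered framewise displacement (mm) and its mean over all TRs."""

    fd_mm: np.ndarray
    mean_fd: float = field(init=False)

    def __post_init__(self) -> None:
        self.fd_mm = np.asarray(self.fd_mm, dtype=float)
        if np.any(self.fd_mm < 0):
            raise DataError("framewise displacement must be non-negative")
        self.mean_fd = float(self.fd_mm.mean())


@dataclass
class RoiTimecourseSet:
    """T x R ROI series with the ROI -> network map and the subject's censor mask."""

    values: np.ndarray
    roi_labels: Sequence[str]
    network_of: Mapping[str, str]
    tr_seconds: float
    censor: CensorMask | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.roi_labels = list(self.roi_labels)
        if self.values.ndim != 2 or self.values.shape[1] != len(self.roi_labels):
            raise DataError("values must be T x len(roi_labels)")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise DataError("ROI labels must be unique")
        missing = [r for r in self.roi_labels if r not in self.network_of]
        if missing:
            raise DataError(f"ROIs without a network assignment: {missing}")
        if self.censor is None:
            self.censor = CensorMask.none(self.values.shape[0])
        if self.censor.n_timepoints != self.values.shape[0]:
            raise DataError("censor mask length must equal number of timepoints")

    @property
    def n_timepoints(self) -> int:
        return self.values.shape[0]

    @property
    def networks(self) -> list[str]:
        seen: list[str] = []
        for r in self.roi_labels:
            n = self.network_of[r]
            if n not in seen:
                seen.append(n)
        return seen

    def rois_in(self, network: str) -> list[str]:
        return [r for r in self.roi_labels if self.network_of[r] == network]

    def column(self, roi: str) -> np.ndarray:
        return self.values[:, self.roi_labels.index(roi)]

    def with_values(self, values: np.ndarray) -> "RoiTimecourseSet":
        return RoiTimecourseSet(
            values=values,
            roi_labels=self.roi_labels,
            network_of=dict(self.network_of),
            tr_seconds=self.tr_seconds,
            censor=CensorMask(self.censor.censored.copy()),
        )


@dataclass
class NetworkTimecourse:
    """A subject's network-average series; inherits the subject's censor mask."""

    values: np.ndarray
    network: str
    censor: CensorMask

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("network timecourse must be 1-D")
        if self.censor.n_timepoints != self.values.shape[0]:
            raise DataError("censor mask length must equal series length")
        valid = self.values[~self.censor.censored]
        if valid.size and not np.all(np.isfinite(valid)):
            raise DataError("non-finite values at uncensored timepoints")


@dataclass
class EvokedTemplates:
    """Stimulus-evoked structure shared by all simulated subjects.

    ``evoked`` maps network label -> zero-mean unit-variance series;
    ``shared`` is the audiovisual component common to both networks;
    ``event_table`` holds (label, start TR, end TR) with end exclusive,
    including the final mental-state event "T04" placed at the ToM
    template's largest excursion.
    """

    evoked: dict[str, np.ndarray]
    shared: np.ndarray
    event_table: list[tuple[str, int, int]]
    tr_seconds: float

    def event_window(self, label: str) -> tuple[int, int]:
        for name, start, end in self.event_table:
            if name == label:
                return start, end
        raise DataError(f"unknown event label: {label}")


@dataclass
class IRCSummary:
    """Per-subject inter-region correlation summaries (Fisher z)."""

    within_tom_z: float
    within_pain_z: float
    across_z: float


@dataclass
class ExclusionReport:
    """Per-subject motion-QC flags and the per-site thresholds used."""

    flags: pd.DataFrame  # index: subject id; bool columns below
    site_thresholds: dict[str, float]

    COLUMNS = ("iqr_outlier", "over_one_third", "matched_removed")

    def __post_init__(self) -> None:
        for col in self.COLUMNS:
            if col not in self.flags.columns:
                raise DataError(f"exclusion flags missing column {col}")

    @property
    def excluded(self) -> list:
        mask = self.flags[list(self.COLUMNS)].any(axis=1)
        return list(self.flags.index[mask])

    @property
    def kept(self) -> list:
        mask = self.flags[list(self.COLUMNS)].any(axis=1)
        return list(self.flags.index[~mask])


@dataclass
class ModelResult:
    """A fitted linear model: one row per term plus bookkeeping.

    ``terms`` columns: beta, se, t, p, d (and beta_raw/se_raw when the model
    was fitted on standardized variables).  ``pruned`` lists interaction
    terms dropped during refitting.
    """

    terms: pd.DataFrame
    n: int
    pruned: list[str]
    family: str
    bic: float
    r_squared: float

    def __post_init__(self) -> None:
        p = self.terms["p"].to_numpy()
        if np.any((p < 0) | (p > 1)):
            raise DataError("p-values must lie in [0, 1]")

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]
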