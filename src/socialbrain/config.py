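"""Simulation and run configuration.

The synthetic-cohort defaults are the package's stated world: a two-group
(ASD / neurotypical) movie-watching cohort scanned at two sites with a
multiband TR of 0.72 s, six Theory-of-Mind ROIs and seven Pain-matrix ROIs.
Behavioral score distributions follow the published cohort description
(group means/SDs for AQ, MASC, EQ); neural loadings, noise scales and the
brain-behavior coupling are simulation choices documented in the methods
note.  Defaults are configurable but deliberately not tuned per analysis.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

from .errors import ConfigError

#: ROI -> network map for the default 13-region social-brain atlas.
DEFAULT_ROI_NETWORKS: dict[str, str] = {
    "dMPFC": "ToM",
    "mMPFC": "ToM",
    "vMPFC": "ToM",
    "PC": "ToM",
    "rTPJ": "ToM",
    "lTPJ": "ToM",
    "AMCC": "Pain",
    "rIns": "Pain",
    "lIns": "Pain",
    "rMFG": "Pain",
    "lMFG": "Pain",
    "rS2": "Pain",
    "lS2": "Pain",
}

#: Evoked-signal loading per (group, network); NT exceeds ASD on both
#: networks so within-NT > across-group > within-ASD similarity holds in
#: expectation, with the larger gap in the ToM network.
DEFAULT_LOADINGS: dict[tuple[str, str], float] = {
    ("NT", "ToM"): 0.60,
    ("NT", "Pain"): 0.65,
    ("ASD", "ToM"): 0.40,
    ("ASD", "Pain"): 0.50,
}

DEFAULT_N_PER_GROUP: dict[str, int] = {"ASD": 34, "NT": 73}

#: Behavioral score distributions per group: mean, sd.
DEFAULT_SCORE_DISTRIBUTIONS: dict[str, dict[str, tuple[float, float]]] = {
    "AQ": {"ASD": (27.9, 9.2), "NT": (16.4, 6.8)},
    "MASC": {"ASD": (29.4, 8.8), "NT": (35.5, 3.5)},
    "EQ": {"ASD": (33.1, 17.1), "NT": (47.3, 14.1)},
}
DEFAULT_AGE = (27.3, 6.6)
DEFAULT_FSIQ = (110.8, 11.6)
DEFAULT_FEMALE_FRAC = {"ASD": 11 / 34, "NT": 23 / 73}
DEFAULT_SITES = ("IU", "Caltech")


@dataclass(frozen=True)
class BehaviorCoupling:
    """Couple a behavioral score to a neural metric in one group.

    ``rho`` is the target correlation between the score and the metric
    within ``group`` (None = all subjects).
    """

    metric: str
    rho: float
    group: str | None = None


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort generator."""

    n_per_group: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_GROUP)
    )
    n_timepoints: int = 548
    tr_seconds: float = 0.72
    roi_networks: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_ROI_NETWORKS)
    )
    loading_by_group_network: dict[tuple[str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_LOADINGS)
    )
    cross_network_leak: float = 0.15
    shared_loading: float = 0.30
    idio_sd: float = 0.80
    noise_sd: float = 0.50
    template_smooth_s: float = 10.0  # FWHM of the Gaussian smoothing kernel
    template_corr_bound: float = 0.10

    # motion model
    walk_step_mm: float = 0.01
    resp_amp_mm: float = 0.05
    resp_hz: float = 0.33
    artifact_rate: float = 0.01  # per-TR spike probability
    artifact_fd_mm: float = 2.0
    artifact_bold_amp: float = 3.0  # z units, shared across ROIs at spike TRs

    # behavior model
    behavior_coupling: dict[str, BehaviorCoupling] = field(
        default_factory=lambda: {
            "MASC": BehaviorCoupling(metric="within_tom_z", rho=0.6, group="NT")
        }
    )
    score_distributions: dict[str, dict[str, tuple[float, float]]] = field(
        default_factory=lambda: {
            k: dict(v) for k, v in DEFAULT_SCORE_DISTRIBUTIONS.items()
        }
    )
    age_mean_sd: tuple[float, float] = DEFAULT_AGE
    fsiq_mean_sd: tuple[float, float] = DEFAULT_FSIQ
    female_frac: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_FEMALE_FRAC)
    )
    sites: tuple[str, ...] = DEFAULT_SITES

    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_timepoints <= 8:
            raise ConfigError("n_timepoints must exceed 8")
        if self.tr_seconds <= 0:
            raise ConfigError("tr_seconds must be positive")
        networks = sorted(set(self.roi_networks.values()))
        if len(networks) != 2:
            raise ConfigError(
                f"roi_networks must cover exactly two networks, got {networks}"
            )
        for name in (
            "cross_network_leak",
            "shared_loading",
            "idio_sd",
            "noise_sd",
            "walk_step_mm",
            "resp_amp_mm",
            "artifact_rate",
            "artifact_fd_mm",
            "artifact_bold_amp",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        for key, value in self.loading_by_group_network.items():
            if value < 0:
                raise ConfigError(f"loading {key} must be >= 0")
        for group in self.n_per_group:
            for network in networks:
                if (group, network) not in self.loading_by_group_network:
                    raise ConfigError(f"missing loading for {(group, network)}")
        if any(n < 1 for n in self.n_per_group.values()):
            raise ConfigError("every group needs at least one subject")

    @property
    def network_labels(self) -> tuple[str, str]:
        seen: list[str] = []
        for roi in self.roi_networks:
            n = self.roi_networks[roi]
            if n not in seen:
                seen.append(n)
        return tuple(seen)  # type: ignore[return-value]

    @property
    def groups(self) -> list[str]:
        return list(self.n_per_group)


@dataclass
class MotionSettings:
    band_hz: tuple[float, float] = (0.31, 0.43)
    radius_mm: float = 50.0
    bypass_filter: bool = False
    diff_mode: str = "lag4"  # or "sum4": sum of four lag-1 steps
    threshold_mm: float = 0.5
    pad: int = 2
    fixed_thresholds: dict[str, float] | None = None
    match_alpha: float = 0.05
    match_metrics: tuple[str, ...] = ("mean_fd", "n_censored")


@dataclass
class PrepSettings:
    highpass_cutoff_s: float = 100.0
    filter_order: int = 5


@dataclass
class MetricSettings:
    reference_group: str = "NT"
    min_joint_timepoints: int = 10
    event_label: str = "T04"


@dataclass
class BatterySettings:
    prune_alpha: float = 0.05
    standardize: bool = True
    null_evidence_models: tuple[str, ...] = (
        "irc_within_pain_group",
        "irc_across_group",
        "sim_nt_pain_group",
    )


@dataclass
class RunConfig:
    """Full pipeline configuration (synthetic or real mode)."""

    mode: str = "synthetic"
    sim: SimConfig = field(default_factory=SimConfig)
    motion: MotionSettings = field(default_factory=MotionSettings)
    prep: PrepSettings = field(default_factory=PrepSettings)
    metrics: MetricSettings = field(default_factory=MetricSettings)
    battery: BatterySettings = field(default_factory=BatterySettings)
    out_dir: str = "results/run"
    seed: int = 0
    make_plots: bool = False
    # real-mode inputs
    cohort_csv: str | None = None
    timecourse_dir: str | None = None
    motion_dir: str | None = None
    event_table: str | None = None
    atlas_map: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "real"):
            raise ConfigError("mode must be 'synthetic' or 'real'")
        if self.mode == "real":
            required = ("cohort_csv", "timecourse_dir", "motion_dir", "atlas_map")
            missing = [k for k in required if getattr(self, k) is None]
            if missing:
                raise ConfigError(f"real mode requires paths: {missing}")
        # the pipeline seed overrides the sim seed so one knob controls all
        self.sim = dataclasses.replace(self.sim, seed=self.seed)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def config_to_dict(config) -> dict:
    return _jsonable(config)


def config_hash(config) -> str:
    """Hash of the scientific configuration (output location excluded)."""
    payload = config_to_dict(config)
    payload.pop("out_dir", None)
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True).encode()
    ).hexdigest()
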