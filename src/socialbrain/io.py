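"""Plain-text IO: wide TSV timecourses, confounds-style motion TSV,
atlas/event tables, cohort CSV, JSON reports.  Floats are written at full
repr precision so write/read round-trips are exact."""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    CensorMask,
    FDSeries,
    MotionTrace,
    RoiTimecourseSet,
    MOTION_COLUMNS,
)
from .errors import DataError


def write_timecourses(tc: RoiTimecourseSet, path: str | Path) -> None:
    pd.DataFrame(tc.values, columns=tc.roi_labels).to_csv(path, sep="\t", index=False)


def read_timecourses(
    path: str | Path,
    network_of: dict[str, str],
    tr_seconds: float,
    censor: CensorMask | None = None,
) -> RoiTimecourseSet:
    df = pd.read_csv(path, sep="\t")
    return RoiTimecourseSet(
        values=df.to_numpy(dtype=float),
        roi_labels=list(df.columns),
        network_of=network_of,
        tr_seconds=tr_seconds,
        censor=censor,
    )


def write_motion(trace: MotionTrace, path: str | Path) -> None:
    pd.DataFrame(trace.values, columns=list(MOTION_COLUMNS)).to_csv(
        path, sep="\t", index=False
    )


def read_motion(path: str | Path, tr_seconds: float) -> MotionTrace:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in MOTION_COLUMNS if c not in df.columns]
    if missing:
        raise DataError(f"motion file {path} lacks columns {missing}")
    return MotionTrace(
        values=df[list(MOTION_COLUMNS)].to_numpy(dtype=float), tr_seconds=tr_seconds
    )


def write_series(values: np.ndarray, path: str | Path, name: str = "value") -> None:
    pd.DataFrame(
        {"tr_index": np.arange(len(values)), name: np.asarray(values)}
    ).to_csv(path, sep="\t", index=False)


def read_series(path: str | Path, name: str = "value") -> np.ndarray:
    return pd.read_csv(path, sep="\t")[name].to_numpy()


def write_fd(fd: FDSeries, path: str | Path) -> None:
    write_series(fd.fd_mm, path, name="fd_mm")


def read_fd(path: str | Path) -> FDSeries:
    return FDSeries(fd_mm=read_series(path, name="fd_mm"))


def write_mask(mask: CensorMask, path: str | Path) -> None:
    write_series(mask.censored.astype(int), path, name="censored")


def read_mask(path: str | Path) -> CensorMask:
    return CensorMask(read_series(path, name="censored").astype(bool))


def write_events(event_table: list[tuple[str, int, int]], path: str | Path) -> None:
    pd.DataFrame(event_table, columns=["label", "start_tr", "end_tr"]).to_csv(
        path, sep="\t", index=False
    )


def read_events(path: str | Path) -> list[tuple[str, int, int]]:
    df = pd.read_csv(path, sep="\t")
    return [
        (str(r["label"]), int(r["start_tr"]), int(r["end_tr"]))
        for _, r in df.iterrows()
    ]


def write_atlas(network_of: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        {"roi": list(network_of), "network": list(network_of.values())}
    ).to_csv(path, sep="\t", index=False)


def read_atlas(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df["roi"], df["network"]))


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())


def file_sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
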