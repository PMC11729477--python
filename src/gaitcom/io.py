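"""Tidy-CSV readers and writers for every pipeline exchange format.

Marker CSV:  ``time, <MARKER>_X, <MARKER>_Y, <MARKER>_Z`` (metres, X = AP,
Y = ML, Z = vertical).  IMU CSV: ``time, acc_x, acc_y, acc_z`` (m/s^2,
gravity included on z).  Events CSV: ``time_s, source, foot``.  Truth JSON
carries the simulated ground truth (CoM trajectory, heel-strike times,
config echo).  Readers validate schema and sampling uniformity and raise
:class:`~gaitcom.errors.DataError` with the offending column or row.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .body_model import ComTrajectory, MarkerFrameSeries
from .errors import DataError
from .gait_events import EventSeries
from .signal_processing import UniformSeries

__all__ = [
    "write_marker_csv", "read_marker_csv",
    "write_imu_csv", "read_imu_csv",
    "write_events_csv", "read_events_csv",
    "write_truth_json", "read_truth_json",
    "write_trial",
]

#: maximum timestamp jitter tolerated when inferring the sampling rate, s
TIME_JITTER_TOL = 1e-6


def _infer_rate(time: np.ndarray, what: str) -> float:
    if time.size < 2:
        raise DataError(f"{what}: need at least 2 samples to infer a rate")
    dt = np.diff(time)
    if np.any(np.abs(dt - dt[0]) > TIME_JITTER_TOL):
        worst = int(np.argmax(np.abs(dt - dt[0])))
        raise DataError(f"{what}: non-uniform timestamps near row {worst + 1}")
    rate = (time.size - 1) / float(time[-1] - time[0])
    # snap to an integer rate when the float timestamps round-trip one
    if abs(rate - round(rate)) < 1e-6 * max(1.0, rate):
        rate = float(round(rate))
    return rate


def write_marker_csv(markers: MarkerFrameSeries, path) -> None:
    data = {"time": markers.time}
    for name in sorted(markers.positions):
        pos = markers.positions[name]
        for j, suffix in enumerate(("X", "Y", "Z")):
            data[f"{name}_{suffix}"] = pos[:, j]
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def read_marker_csv(path) -> MarkerFrameSeries:
    frame = pd.read_csv(path, float_precision="round_trip")
    if "time" not in frame.columns:
        raise DataError(f"{path}: missing 'time' column")
    names = {}
    for col in frame.columns:
        if col == "time":
            continue
        if "_" not in col or col.rsplit("_", 1)[1] not in ("X", "Y", "Z"):
            raise DataError(f"{path}: unrecognized column {col!r}")
        stem, axis = col.rsplit("_", 1)
        names.setdefault(stem, set()).add(axis)
    positions = {}
    for stem, axes in sorted(names.items()):
        missing = {"X", "Y", "Z"} - axes
        if missing:
            raise DataError(
                f"{path}: marker {stem!r} missing column(s) "
                + ", ".join(f"{stem}_{a}" for a in sorted(missing))
            )
        positions[stem] = frame[[f"{stem}_X", f"{stem}_Y", f"{stem}_Z"]].to_numpy(float)
    time = frame["time"].to_numpy(float)
    rate = _infer_rate(time, str(path))
    return MarkerFrameSeries(rate=rate, positions=positions, t0=float(time[0]))


def write_imu_csv(imu: UniformSeries, path) -> None:
    pd.DataFrame({
        "time": imu.time,
        "acc_x": imu.values[:, 0],
        "acc_y": imu.values[:, 1],
        "acc_z": imu.values[:, 2],
    }).to_csv(path, index=False, float_format="%.17g")


def read_imu_csv(path) -> UniformSeries:
    frame = pd.read_csv(path, float_precision="round_trip")
    for col in ("time", "acc_x", "acc_y", "acc_z"):
        if col not in frame.columns:
            raise DataError(f"{path}: missing column {col!r}")
    time = frame["time"].to_numpy(float)
    rate = _infer_rate(time, str(path))
    values = frame[["acc_x", "acc_y", "acc_z"]].to_numpy(float)
    return UniformSeries(rate=rate, values=values, unit="m/s^2", t0=float(time[0]))


def write_events_csv(events: list[EventSeries], path) -> None:
    rows = [
        {"time_s": t, "source": ev.source, "foot": ev.foot}
        for ev in events
        for t in ev.times
    ]
    pd.DataFrame(rows, columns=["time_s", "source", "foot"]).to_csv(path, index=False)


def read_events_csv(path) -> list[EventSeries]:
    frame = pd.read_csv(path)
    for col in ("time_s", "source", "foot"):
        if col not in frame.columns:
            raise DataError(f"{path}: missing column {col!r}")
    out = []
    for (source, foot), grp in frame.groupby(["source", "foot"], sort=False):
        out.append(EventSeries(times=np.sort(grp["time_s"].to_numpy(float)),
                               source=str(source), foot=str(foot)))
    return out


def write_truth_json(trial, path) -> None:
    payload = {
        "subject_id": trial.subject_id,
        "stride_duration": trial.stride_duration,
        "truth_hs": list(map(float, trial.truth_hs)),
        "com_rate": trial.truth_com.rate,
        "truth_com": np.asarray(trial.truth_com.com).tolist(),
        "config": dataclasses.asdict(trial.config),
    }
    Path(path).write_text(json.dumps(payload))


def read_truth_json(path) -> dict:
    payload = json.loads(Path(path).read_text())
    payload["truth_hs"] = np.asarray(payload["truth_hs"], dtype=float)
    payload["truth_com"] = ComTrajectory(
        rate=float(payload["com_rate"]),
        com=np.asarray(payload["truth_com"], dtype=float),
    )
    return payload


def write_trial(trial, out_dir) -> dict[str, Path]:
    """Write one synthetic trial as the tidy-CSV + truth-JSON bundle."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = trial.subject_id
    paths = {
        "markers": out / f"{stem}_markers.csv",
        "imu": out / f"{stem}_imu.csv",
        "truth": out / f"{stem}_truth.json",
    }
    write_marker_csv(trial.markers, paths["markers"])
    write_imu_csv(trial.imu, paths["imu"])
    write_truth_json(trial, paths["truth"])
    return paths
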