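"""Gait-cycle segmentation, 101-node time normalization, amplitude
normalization to [-1, 1], and assembly of the subject x condition x node x
direction array that feeds the agreement and SPM statistics.

A gait cycle runs from one heel strike to the next heel strike of the same
foot; time normalization maps it onto 0..100 % in 1 % steps (101 nodes) by
cubic-spline interpolation.  The first and last cycle of a trial are
discarded to keep filter edge transients out of the statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .errors import DataError
from .gait_events import EventSeries
from .signal_processing import UniformSeries

__all__ = [
    "GaitCycle",
    "NormalizedCycleSet",
    "segment_cycles",
    "time_normalize",
    "amplitude_normalize",
    "ensemble_average",
    "DIRECTIONS",
    "CONDITIONS",
    "N_NODES",
]

N_NODES = 101
DIRECTIONS = ("AP", "ML", "SI")
CONDITIONS = ("IMU", "ML5", "CoM")


@dataclass
class GaitCycle:
    times: np.ndarray       # sample times covering [t_start, t_end] (plus padding)
    values: np.ndarray      # (n,) or (n, 3)
    t_start: float
    t_end: float

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise DataError("cycle must have t_end > t_start")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


def segment_cycles(
    series: UniformSeries,
    events: EventSeries,
    trim_edges: bool = True,
    pad_samples: int = 2,
) -> list[GaitCycle]:
    """One cycle per consecutive event pair; edge cycles trimmed when possible.

    With at least three raw cycles the first and last are discarded
    (filter-edge trim); with fewer, nothing is trimmed and a warning is
    emitted.
    """
    if len(events) < 2:
        raise DataError(f"need >= 2 events to segment cycles, got {len(events)}")
    t = series.time
    raw: list[GaitCycle] = []
    for t0, t1 in zip(events.times[:-1], events.times[1:]):
        i0 = max(0, int(np.searchsorted(t, t0)) - pad_samples)
        i1 = min(len(t), int(np.searchsorted(t, t1, side="right")) + pad_samples)
        raw.append(GaitCycle(times=t[i0:i1], values=series.values[i0:i1], t_start=t0, t_end=t1))
    if not trim_edges:
        return raw
    if len(raw) >= 3:
        return raw[1:-1]
    warnings.warn(
        f"only {len(raw)} cycle(s); edge cycles kept (no trim)", stacklevel=2
    )
    return raw


def time_normalize(cycle: GaitCycle, n_nodes: int = N_NODES) -> np.ndarray:
    """Resample one cycle onto 0..100 % nodes by cubic-spline interpolation.

    Nodes are placed at ``t_start + k/(n_nodes-1) * duration``; the first
    and last nodes are interpolated at the cycle boundaries (no
    extrapolation, which the padded sample window guarantees).
    """
    if cycle.times.size < 4:
        raise DataError(f"need >= 4 samples per cycle, got {cycle.times.size}")
    nodes = cycle.t_start + np.linspace(0.0, 1.0, n_nodes) * cycle.duration
    if nodes[0] < cycle.times[0] - 1e-12 or nodes[-1] > cycle.times[-1] + 1e-12:
        raise DataError("cycle samples do not cover the cycle span (extrapolation refused)")
    spline = CubicSpline(cycle.times, cycle.values, axis=0)
    return spline(np.clip(nodes, cycle.times[0], cycle.times[-1]))


def amplitude_normalize(curve: np.ndarray) -> np.ndarray:
    """Scale so the largest excursion maps to +/-1 (divide by max absolute value)."""
    curve = np.asarray(curve, dtype=float)
    scale = np.max(np.abs(curve))
    if scale == 0.0:
        warnings.warn("all-zero curve passed to amplitude_normalize; returned unchanged",
                      stacklevel=2)
        return curve.copy()
    return curve / scale


def ensemble_average(curves: list[np.ndarray] | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pointwise mean and sample SD over cycles (SD is zero for a single cycle)."""
    arr = np.asarray(curves, dtype=float)
    if arr.size == 0:
        raise DataError("no cycles to average")
    mean = arr.mean(axis=0)
    if arr.shape[0] == 1:
        warnings.warn("single cycle: SD set to zero", stacklevel=2)
        sd = np.zeros_like(mean)
    else:
        sd = arr.std(axis=0, ddof=1)
    return mean, sd


@dataclass
class NormalizedCycleSet:
    """subject x condition x node x direction acceleration array.

    ``data`` may hold physical accelerations (m/s^2) or [-1, 1] normalized
    curves, flagged by ``normalized``.
    """

    data: np.ndarray                      # (S, C, N_NODES, 3)
    subjects: tuple[str, ...]
    conditions: tuple[str, ...] = CONDITIONS
    directions: tuple[str, ...] = DIRECTIONS
    normalized: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        expected = (len(self.subjects), len(self.conditions), N_NODES, len(self.directions))
        if self.data.shape != expected:
            raise DataError(f"data shape {self.data.shape} != {expected}")
        if self.normalized:
            limit = np.max(np.abs(self.data))
            if limit > 1.0 + 1e-9:
                raise DataError(f"normalized data exceeds [-1, 1] (max |v| = {limit})")

    def condition(self, name: str) -> np.ndarray:
        """(S, N_NODES, 3) slice for one condition."""
        return self.data[:, self.conditions.index(name)]

    def amplitude_normalized(self) -> "NormalizedCycleSet":
        """Per subject, condition and direction, scale the largest excursion to +/-1."""
        out = np.empty_like(self.data)
        for s in range(self.data.shape[0]):
            for c in range(self.data.shape[1]):
                for d in range(self.data.shape[3]):
                    out[s, c, :, d] = amplitude_normalize(self.data[s, c, :, d])
        return NormalizedCycleSet(out, self.subjects, self.conditions, self.directions,
                                  normalized=True)

    def to_long(self) -> pd.DataFrame:
        """Long-format exchange table: subject, condition, direction, node, value."""
        s_i, c_i, n_i, d_i = np.meshgrid(
            np.arange(len(self.subjects)), np.arange(len(self.conditions)),
            np.arange(N_NODES), np.arange(len(self.directions)), indexing="ij",
        )
        return pd.DataFrame({
            "subject": np.asarray(self.subjects)[s_i.ravel()],
            "condition": np.asarray(self.conditions)[c_i.ravel()],
            "direction": np.asarray(self.directions)[d_i.ravel()],
            "node": n_i.ravel(),
            "value": self.data.ravel(),
        })

    @classmethod
    def from_long(cls, frame: pd.DataFrame, normalized: bool = False) -> "NormalizedCycleSet":
        subjects = tuple(pd.unique(frame["subject"]))
        conditions = tuple(pd.unique(frame["condition"]))
        directions = tuple(pd.unique(frame["direction"]))
        data = np.full((len(subjects), len(conditions), N_NODES, len(directions)), np.nan)
        s_idx = {s: i for i, s in enumerate(subjects)}
        c_idx = {c: i for i, c in enumerate(conditions)}
        d_idx = {d: i for i, d in enumerate(directions)}
        data[
            frame["subject"].map(s_idx).to_numpy(),
            frame["condition"].map(c_idx).to_numpy(),
            frame["node"].to_numpy(),
            frame["direction"].map(d_idx).to_numpy(),
        ] = frame["value"].to_numpy()
        if np.isnan(data).any():
            raise DataError("long table does not cover the full subject/condition/node grid")
        return cls(data, subjects, conditions, directions, normalized=normalized)
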