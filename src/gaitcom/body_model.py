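"""Whole-body centre of mass from a 13-link segmental model.

The whole-body CoM is the mass-fraction weighted sum of the segment CoMs,

    x0 = sum_i (m_i / M) * x_i      (and likewise for y0, z0),

where each segment CoM lies a fixed fraction (``com_ratio``) of the way from
the proximal to the distal segment endpoint, and each endpoint is the
centroid of one or more markers.  Default mass fractions and CoM ratios are
the classical Dempster cadaver values as tabulated by Winter, shipped as an
editable YAML table (``data/body_model_dempster.yaml``).
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import yaml

from .errors import DataError, ModelError

__all__ = [
    "SegmentDefinition",
    "BodyModel",
    "MarkerFrameSeries",
    "ComTrajectory",
    "load_body_model",
    "default_body_model",
    "segment_com",
    "whole_body_com",
]

SEGMENT_NAMES = (
    "head_neck",
    "trunk",
    "pelvis",
    "upper_arm_l",
    "upper_arm_r",
    "forearm_hand_l",
    "forearm_hand_r",
    "thigh_l",
    "thigh_r",
    "shank_l",
    "shank_r",
    "foot_l",
    "foot_r",
)

MASS_TOL = 1e-6


@dataclass(frozen=True)
class SegmentDefinition:
    name: str
    proximal_markers: tuple[str, ...]
    distal_markers: tuple[str, ...]
    mass_fraction: float
    com_ratio: float

    def __post_init__(self) -> None:
        if self.mass_fraction <= 0:
            raise ModelError(f"segment {self.name}: mass_fraction must be > 0")
        if not 0.0 <= self.com_ratio <= 1.0:
            raise ModelError(f"segment {self.name}: com_ratio must be in [0, 1]")
        if not self.proximal_markers or not self.distal_markers:
            raise ModelError(f"segment {self.name}: endpoint marker lists must be non-empty")


@dataclass(frozen=True)
class BodyModel:
    """An ordered collection of exactly 13 segment definitions summing to unit mass."""

    segments: tuple[SegmentDefinition, ...]

    def __post_init__(self) -> None:
        if len(self.segments) != 13:
            raise ModelError(f"body model must have 13 segments, got {len(self.segments)}")
        names = {s.name for s in self.segments}
        if names != set(SEGMENT_NAMES):
            raise ModelError(f"unexpected segment names: {sorted(names ^ set(SEGMENT_NAMES))}")
        total = sum(s.mass_fraction for s in self.segments)
        if abs(total - 1.0) > MASS_TOL:
            raise ModelError(f"mass fractions sum to {total!r}, expected 1 +/- {MASS_TOL}")

    @property
    def total_mass_fraction(self) -> float:
        return float(sum(s.mass_fraction for s in self.segments))

    @property
    def marker_names(self) -> set[str]:
        out: set[str] = set()
        for seg in self.segments:
            out.update(seg.proximal_markers)
            out.update(seg.distal_markers)
        return out

    def segment(self, name: str) -> SegmentDefinition:
        for seg in self.segments:
            if seg.name == name:
                return seg
        raise KeyError(name)


@dataclass
class MarkerFrameSeries:
    """Named 3-D marker trajectories at a fixed sampling rate (metres)."""

    rate: float
    positions: dict[str, np.ndarray]  # marker name -> (n_frames, 3)
    t0: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise DataError(f"marker rate must be positive, got {self.rate}")
        lengths = {name: np.asarray(p).shape for name, p in self.positions.items()}
        n = None
        for name, shape in lengths.items():
            if len(shape) != 2 or shape[1] != 3:
                raise DataError(f"marker {name}: expected (n, 3) positions, got {shape}")
            if n is None:
                n = shape[0]
            elif shape[0] != n:
                raise DataError(f"marker {name}: frame count {shape[0]} != {n}")
        self.positions = {k: np.asarray(v, dtype=float) for k, v in self.positions.items()}

    @property
    def n_frames(self) -> int:
        return next(iter(self.positions.values())).shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.n_frames) / self.rate

    def require(self, names) -> None:
        missing = sorted(set(names) - set(self.positions))
        if missing:
            raise DataError(f"missing markers: {missing}")


@dataclass
class ComTrajectory:
    rate: float
    com: np.ndarray  # (n_frames, 3), metres
    t0: float = 0.0

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(self.com.shape[0]) / self.rate


def load_body_model(path=None) -> BodyModel:
    """Load a body model from YAML; with no path, load the shipped Dempster table."""
    if path is None:
        text = (
            resources.files("gaitcom").joinpath("data/body_model_dempster.yaml").read_text()
        )
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    segments = tuple(
        SegmentDefinition(
            name=entry["name"],
            proximal_markers=tuple(entry["proximal_markers"]),
            distal_markers=tuple(entry["distal_markers"]),
            mass_fraction=float(entry["mass_fraction"]),
            com_ratio=float(entry["com_ratio"]),
        )
        for entry in raw["segments"]
    )
    return BodyModel(segments=segments)


_DEFAULT_MODEL: BodyModel | None = None


def default_body_model() -> BodyModel:
    global _DEFAULT_MODEL
    if _DEFAULT_MODEL is None:
        _DEFAULT_MODEL = load_body_model()
    return _DEFAULT_MODEL


def _endpoint(markers: MarkerFrameSeries, names: tuple[str, ...], frame=None) -> np.ndarray:
    stack = []
    for name in names:
        if name not in markers.positions:
            raise DataError(f"missing marker {name!r}" + (f" at frame {frame}" if frame is not None else ""))
        pos = markers.positions[name]
        stack.append(pos if frame is None else pos[frame])
    return np.mean(stack, axis=0)


def segment_com(segment: SegmentDefinition, markers: MarkerFrameSeries, frame: int | None = None) -> np.ndarray:
    """Segment CoM: proximal + com_ratio * (distal - proximal).

    With ``frame=None`` the full trajectory ``(n_frames, 3)`` is returned.
    """
    prox = _endpoint(markers, segment.proximal_markers, frame)
    dist = _endpoint(markers, segment.distal_markers, frame)
    return prox + segment.com_ratio * (dist - prox)


def whole_body_com(model: BodyModel, markers: MarkerFrameSeries) -> ComTrajectory:
    """Whole-body CoM trajectory as the mass-weighted sum of segment CoMs."""
    total = sum(s.mass_fraction for s in model.segments)
    if abs(total - 1.0) > MASS_TOL:  # defensive: frozen dataclass already checks
        raise ModelError(f"mass fractions sum to {total}")
    markers.require(model.marker_names)
    com = np.zeros((markers.n_frames, 3))
    for seg in model.segments:
        com += seg.mass_fraction * segment_com(seg, markers)
    return ComTrajectory(rate=markers.rate, com=com, t0=markers.t0)
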