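"""Heel-strike / initial-contact detection and cross-system event pairing.

Camera side: heel strikes from a vertical ground-reaction-force threshold
crossing when a force series is available, otherwise from local minima of
the heel-marker height (kinematic fallback).

IMU side: the wavelet approach of McCamley and colleagues — detrend the
gravity-corrected vertical acceleration, integrate it to a vertical
velocity, then differentiate by a continuous wavelet transform with a
Gaussian-derivative (``gaus1``) mother wavelet at a scale tied to the
stride period; initial contacts are the local minima of the transformed
signal.  Note the detector fires once per *step* (both feet); selecting a
single foot's events is done downstream against the camera reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt
from scipy import signal as sig
from scipy.integrate import cumulative_trapezoid

from .errors import DetectionError, SynchronizationError
from .signal_processing import UniformSeries

__all__ = [
    "EventSeries",
    "MatchResult",
    "dominant_stride_period",
    "detect_hs_camera",
    "detect_hs_imu",
    "match_events",
]

GRF_THRESHOLD_N = 20.0
#: minimum event separation, as a fraction of the dominant stride period
REFRACTORY_FRAC = 0.5
#: CWT scale as a fraction of the stride period
CWT_SCALE_FRAC = 0.1
STRIDE_BAND_HZ = (0.5, 2.0)


@dataclass
class EventSeries:
    times: np.ndarray
    source: str                  # "camera" | "imu"
    foot: str = "unspecified"    # "left" | "right" | "unspecified"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise DetectionError("event times must be strictly increasing")

    def __len__(self) -> int:
        return self.times.size


def _parabolic_refine(y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample extremum location by parabolic interpolation around idx."""
    idx = np.asarray(idx)
    out = idx.astype(float)
    ok = (idx > 0) & (idx < len(y) - 1)
    i = idx[ok]
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    shift = np.zeros_like(i, dtype=float)
    nz = np.abs(denom) > 1e-30
    shift[nz] = 0.5 * (y[i - 1] - y[i + 1])[nz] / denom[nz]
    out[ok] = i + np.clip(shift, -0.5, 0.5)
    return out


def dominant_stride_period(x: np.ndarray, rate: float) -> float:
    """Dominant stride period (s) from the spectrum of a gait signal.

    The strongest spectral peak of trunk acceleration may sit at the step
    frequency (twice per stride); peaks whose half-frequency falls in the
    stride band are folded down accordingly.
    """
    x = np.asarray(x, dtype=float)
    x = x - x.mean()
    if x.size < 8 or not np.any(np.abs(x) > 0):
        raise DetectionError("series too short or flat for periodicity analysis")
    freqs = np.fft.rfftfreq(x.size, d=1.0 / rate)
    power = np.abs(np.fft.rfft(x * np.hanning(x.size))) ** 2
    power[freqs < 0.2] = 0.0
    f_dom = freqs[int(np.argmax(power))]
    lo, hi = STRIDE_BAND_HZ
    if lo <= f_dom <= hi:
        return 1.0 / f_dom
    if lo <= f_dom / 2.0 <= hi:
        return 2.0 / f_dom
    raise DetectionError(
        f"dominant frequency {f_dom:.2f} Hz outside the stride band {STRIDE_BAND_HZ} Hz"
    )


def detect_hs_camera(
    heel_height: UniformSeries | None = None,
    vertical_grf: UniformSeries | None = None,
    grf_threshold: float = GRF_THRESHOLD_N,
) -> EventSeries:
    """Camera-side heel strikes from GRF (preferred) or heel kinematics."""
    if vertical_grf is not None:
        f = np.asarray(vertical_grf.values, dtype=float)
        above = f >= grf_threshold
        rising = np.flatnonzero(~above[:-1] & above[1:]) + 1
        if above.size and above[0]:
            rising = np.concatenate([[0], rising])
        if rising.size == 0:
            raise DetectionError(
                f"vertical GRF never rises through {grf_threshold} N "
                f"(max {f.max():.1f} N)"
            )
        times = vertical_grf.t0 + rising / vertical_grf.rate
        return EventSeries(times=times, source="camera")
    if heel_height is None:
        raise DetectionError("need a heel-height series or a vertical GRF series")
    z = np.asarray(heel_height.values, dtype=float)
    period = dominant_stride_period(z, heel_height.rate)
    distance = max(1, int(REFRACTORY_FRAC * period * heel_height.rate))
    idx, _ = sig.find_peaks(-z, distance=distance)
    if idx.size == 0:
        raise DetectionError("no heel-height minima found")
    refined = _parabolic_refine(-z, idx)
    times = heel_height.t0 + refined / heel_height.rate
    return EventSeries(times=times, source="camera")


def detect_hs_imu(
    vertical_acc: UniformSeries,
    scale_frac: float = CWT_SCALE_FRAC,
) -> EventSeries:
    """Initial contacts from gravity-corrected vertical trunk acceleration.

    Pipeline: detrend -> trapezoidal integration (velocity) -> CWT
    differentiation with a Gaussian-derivative wavelet at
    ``scale_frac * stride period`` -> local minima separated by at least
    half the dominant stride period.  Invariant to constant offsets (the
    detrend step) and equivariant to time shifts.
    """
    a = np.asarray(vertical_acc.values, dtype=float)
    rate = vertical_acc.rate
    period = dominant_stride_period(a, rate)
    a = a - a.mean()
    v = cumulative_trapezoid(a, dx=1.0 / rate, initial=0.0)
    v = sig.detrend(v)
    scale = max(1.0, scale_frac * period * rate)
    coef, _ = pywt.cwt(v, [scale], "gaus1", sampling_period=1.0 / rate)
    # gaus1 CWT of the velocity approximates -d/dt (smoothed velocity); flip
    # so minima of the transform sit at the downward acceleration peaks
    d = -coef[0]
    distance = max(1, int(REFRACTORY_FRAC * period * rate))
    idx, _ = sig.find_peaks(-d, distance=distance)
    if idx.size == 0:
        raise DetectionError("no initial-contact minima in the transformed signal")
    refined = _parabolic_refine(-d, idx)
    times = vertical_acc.t0 + refined / rate
    return EventSeries(times=times, source="imu")


@dataclass
class MatchResult:
    pairs: list[tuple[int, int]]          # (camera index, imu index)
    offset: float                          # imu clock minus camera clock, s
    unpaired_camera: list[int] = field(default_factory=list)
    unpaired_imu: list[int] = field(default_factory=list)

    @property
    def paired_times(self) -> np.ndarray:
        return np.array([], dtype=float).reshape(0, 2) if not self.pairs else np.array(
            [[ci, ii] for ci, ii in self.pairs], dtype=int
        )


def match_events(camera: EventSeries, imu: EventSeries, tolerance: float = 0.05) -> MatchResult:
    """Pair events across systems after removing the constant clock offset.

    The offset is the median of nearest-neighbour time differences
    (imu minus camera); pairing is greedy nearest-neighbour within
    ``tolerance`` on offset-corrected times.  Unpaired events are reported,
    never silently dropped.
    """
    if len(camera) == 0 or len(imu) == 0:
        raise SynchronizationError("both event series must be non-empty")
    tc, ti = camera.times, imu.times
    nearest = np.array([ti[np.argmin(np.abs(ti - t))] - t for t in tc])
    offset = float(np.median(nearest))
    ti_corr = ti - offset

    candidates = sorted(
        ((abs(ti_corr[j] - tc[i]), i, j) for i in range(len(tc)) for j in range(len(ti))),
    )
    used_c, used_i, pairs = set(), set(), []
    for dist, i, j in candidates:
        if dist > tolerance:
            break
        if i in used_c or j in used_i:
            continue
        pairs.append((i, j))
        used_c.add(i)
        used_i.add(j)
    if not pairs:
        raise SynchronizationError(
            f"no event pairs within {tolerance} s (offset estimate {offset:.3f} s)"
        )
    pairs.sort()
    return MatchResult(
        pairs=pairs,
        offset=offset,
        unpaired_camera=sorted(set(range(len(tc))) - used_c),
        unpaired_imu=sorted(set(range(len(ti))) - used_i),
    )
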