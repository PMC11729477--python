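"""Signal conditioning: zero-lag Butterworth filtering, finite differences,
gravity correction.

Conventions
-----------
* A "fourth-order zero-lag" filter is realised as a second-order Butterworth
  design applied forward and backward (``scipy.signal.filtfilt``), the usual
  convention in gait analysis: the forward-backward pass doubles the effective
  order and cancels the phase.  ``FilterSpec.order`` is the *effective* order
  after doubling; set ``order_convention="design"`` to treat it as the design
  order instead (the filter is then applied forward-backward at that order).
* Axes are x = anteroposterior, y = mediolateral, z = vertical throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .errors import DataError, FilterSpecError

__all__ = [
    "FilterSpec",
    "UniformSeries",
    "butterworth_zero_lag",
    "finite_difference",
    "gravity_correct",
]

#: index of the vertical axis in 3-vector series
VERTICAL_AXIS = 2


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass Butterworth specification.

    Parameters
    ----------
    order : int
        Effective filter order (after the forward-backward doubling when
        ``order_convention == "effective"``).  Must be even in that case.
    cutoff : float
        Cutoff frequency in Hz; must satisfy ``0 < cutoff < rate / 2``.
    rate : float
        Sampling rate of the series the filter will be applied to, Hz.
    zero_lag : bool
        Forward-backward application (the only mode implemented; kept
        explicit because it is part of the processing contract).
    order_convention : str
        ``"effective"`` (default) or ``"design"`` — see module docstring.
    """

    order: int
    cutoff: float
    rate: float
    zero_lag: bool = True
    order_convention: str = "effective"

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise FilterSpecError(f"sampling rate must be positive, got {self.rate}")
        if not 0 < self.cutoff < self.rate / 2:
            raise FilterSpecError(
                f"cutoff {self.cutoff} Hz must lie in (0, Nyquist={self.rate / 2} Hz)"
            )
        if self.order_convention not in ("effective", "design"):
            raise FilterSpecError(f"unknown order convention {self.order_convention!r}")
        if self.order_convention == "effective" and self.order % 2:
            raise FilterSpecError(
                "effective order must be even (forward-backward pass doubles the design order)"
            )
        if self.order < 1:
            raise FilterSpecError("order must be >= 1")

    @property
    def design_order(self) -> int:
        """Order of the underlying single-pass Butterworth design."""
        if self.order_convention == "effective":
            return max(1, self.order // 2)
        return self.order


@dataclass
class UniformSeries:
    """A uniformly sampled series of scalars or 3-vectors.

    ``values`` has shape ``(n,)`` or ``(n, 3)``; time of sample *i* is
    ``i / rate + t0``.
    """

    rate: float
    values: np.ndarray
    unit: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.rate <= 0:
            raise DataError(f"sampling rate must be positive, got {self.rate}")
        if self.values.ndim not in (1, 2):
            raise DataError("values must be a 1-D scalar or (n, 3) vector series")
        if self.values.ndim == 2 and self.values.shape[1] != 3:
            raise DataError(f"vector series must have 3 columns, got {self.values.shape[1]}")

    def __len__(self) -> int:
        return self.values.shape[0]

    @property
    def time(self) -> np.ndarray:
        return self.t0 + np.arange(len(self)) / self.rate

    def copy_with(self, values: np.ndarray, unit: str | None = None) -> "UniformSeries":
        return UniformSeries(self.rate, values, self.unit if unit is None else unit, self.t0)


def butterworth_zero_lag(series: UniformSeries, spec: FilterSpec) -> UniformSeries:
    """Zero-lag (forward-backward) low-pass Butterworth filter.

    Reflective edge padding of three times the filter's characteristic
    length (``filtfilt`` default) suppresses end transients; output length
    equals input length and the passband gain is ~1 with zero net phase.
    """
    if abs(spec.rate - series.rate) > 1e-9:
        raise FilterSpecError(
            f"filter designed for {spec.rate} Hz applied to a {series.rate} Hz series"
        )
    sos = signal.butter(spec.design_order, spec.cutoff, btype="low", fs=spec.rate, output="sos")
    # sosfiltfilt pads by reflection; require enough samples for the pad.
    padlen = 3 * (2 * sos.shape[0] + 1)
    if len(series) <= padlen:
        raise DataError(
            f"series of {len(series)} samples too short for zero-lag filtering "
            f"(needs > {padlen})"
        )
    filtered = signal.sosfiltfilt(sos, series.values, axis=0)
    return series.copy_with(filtered)


def _second_difference(x: np.ndarray, dt: float) -> np.ndarray:
    out = np.empty_like(x)
    out[1:-1] = (x[2:] - 2.0 * x[1:-1] + x[:-2]) / dt**2
    # second-order one-sided stencils at the ends
    out[0] = (2.0 * x[0] - 5.0 * x[1] + 4.0 * x[2] - x[3]) / dt**2
    out[-1] = (2.0 * x[-1] - 5.0 * x[-2] + 4.0 * x[-3] - x[-4]) / dt**2
    return out


_DERIV_UNIT = {"m": {1: "m/s", 2: "m/s^2"}, "m/s": {1: "m/s^2"}}


def finite_difference(series: UniformSeries, deriv_order: int = 1) -> UniformSeries:
    """Finite-difference differentiation.

    Interior samples use central differences (exact for quadratics); the
    endpoints use second-order one-sided stencils, so the output has the
    same length as the input.
    """
    if deriv_order not in (1, 2):
        raise ValueError("deriv_order must be 1 or 2")
    n_min = 3 if deriv_order == 1 else 4
    if len(series) < n_min:
        raise DataError(f"need at least {n_min} samples to differentiate, got {len(series)}")
    dt = 1.0 / series.rate
    if deriv_order == 1:
        out = np.gradient(series.values, dt, axis=0, edge_order=2)
    else:
        out = _second_difference(series.values, dt)
    unit = _DERIV_UNIT.get(series.unit, {}).get(deriv_order, "")
    return series.copy_with(out, unit=unit)


def gravity_correct(imu: UniformSeries, g: float = 9.81) -> UniformSeries:
    """Remove the gravitational offset from the vertical (z) channel.

    A stationary upright sensor reads ``(0, 0, g)``; subtracting *g* from the
    vertical axis leaves purely kinematic acceleration.  Horizontal channels
    are untouched.
    """
    if imu.values.ndim != 2:
        raise DataError("gravity correction expects a 3-vector series")
    corrected = imu.values.copy()
    corrected[:, VERTICAL_AXIS] -= g
    return imu.copy_with(corrected)
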