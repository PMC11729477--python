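"""Synthetic walking trials with analytically known ground truth.

A 13-link body walks along the +x (anteroposterior) axis.  Every segment
endpoint follows a closed-form trajectory

    p(t) = base + (speed * t) e_x + sum_h amp_h * sin(mult_h * w * t + phase_h) e_axis

with fundamental ``w = 2*pi / stride_duration``.  Anteroposterior and
vertical oscillations ride at twice the stride frequency (one per step),
mediolateral sway at the stride frequency; left-side markers are the
right-side trajectories time-shifted by half a stride (phase shift
``mult * pi``).  Markers sit exactly at the segment endpoints, then receive
i.i.d. Gaussian noise.

Ground truth shipped with each trial:

* ``truth_com`` — the exact mass-weighted CoM of the noise-free body;
* ``truth_hs`` — heel-strike times, the analytic minima of the tracked
  (right) virtual heel-marker height, one per stride;
* the virtual IMU channel — the analytic second derivative of the pelvis
  segment CoM displaced by the sensor offset (a constant displacement on a
  translating segment, so the acceleration is the pelvis-CoM acceleration
  itself), expressed in a sensor frame yawed by ``axis_misalignment_deg``
  about the vertical, with gravity added to the vertical channel.

The generator aligns the minima of the pelvis vertical acceleration with
the heel-strike instants (as in real gait, where initial contact coincides
with the downward acceleration peak of the trunk), so IMU-side event
detection can be validated against ``truth_hs``.

Per-subject variation: stride duration is drawn from a (3-sigma truncated)
normal, and each harmonic's amplitude and phase receive small random
perturbations, giving between-subject waveform variability while the
harmonics that define event timing keep their phases.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .body_model import BodyModel, ComTrajectory, MarkerFrameSeries, default_body_model
from .errors import ConfigurationError, DomainError
from .signal_processing import UniformSeries

__all__ = [
    "GaitSimConfig",
    "SyntheticTrial",
    "generate_trial",
    "generate_cohort",
    "analytic_com",
    "analytic_pelvis_acceleration",
]

TWO_PI = 2.0 * math.pi

#: fraction of the stride at which the first (right) heel strike occurs
HS_PHASE_FRAC = 0.15
#: phase of the central vertical double-frequency harmonic that puts the
#: pelvis downward-acceleration peaks on the heel-strike instants
PHASE_VERTICAL = 0.5 * math.pi - 2.0 * TWO_PI * HS_PHASE_FRAC  # = -0.1*pi
#: phase of the (right) heel-height fundamental putting its minima on HS
PHASE_HEEL = -0.5 * math.pi - TWO_PI * HS_PHASE_FRAC
#: trial length in strides beyond the last heel strike margin
TRIAL_MARGIN_STRIDES = 0.05


@dataclass(frozen=True)
class GaitSimConfig:
    """Study conditions for the synthetic cohort.

    Defaults emulate the experimental setup being modelled: 16 healthy
    adults walking at self-selected speed, optical capture at 240 Hz,
    a lumbar IMU at 128 Hz, ~1 mm marker noise.
    """

    n_subjects: int = 16
    n_strides: int = 12
    stride_duration: float = 1.1          # s, cohort mean
    stride_duration_sd: float = 0.08      # s, between-subject SD
    walking_speed: float = 1.3            # m/s
    marker_rate: float = 240.0            # Hz
    imu_rate: float = 128.0               # Hz
    marker_noise_sd: float = 0.001        # m
    imu_noise_sd: float = 0.1             # m/s^2
    sensor_offset: tuple[float, float, float] = (-0.08, 0.0, 0.03)  # m
    axis_misalignment_deg: float = 2.0    # yaw of sensor frame about vertical
    gravity: float = 9.81                 # m/s^2
    seed: int = 0
    amp_jitter: float = 0.12              # relative SD of per-subject amplitude scaling
    phase_jitter: float = 0.25            # rad SD on non-timing harmonics
    oscillation_scale: float = 1.0        # global scale on all oscillation amplitudes
    rigid_body: bool = False              # all markers share one rigid motion
    imu_mode: str = "analytic"            # "analytic" | "from_com" (finite-difference)

    def __post_init__(self) -> None:
        if self.marker_rate <= 0 or self.imu_rate <= 0:
            raise ConfigurationError("sampling rates must be positive")
        if self.stride_duration <= 0:
            raise ConfigurationError("stride_duration must be positive")
        if self.n_strides < 3:
            raise ConfigurationError("n_strides must be >= 3")
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.stride_duration_sd < 0 or self.marker_noise_sd < 0 or self.imu_noise_sd < 0:
            raise ConfigurationError("noise SDs must be non-negative")
        if self.imu_mode not in ("analytic", "from_com"):
            raise ConfigurationError(f"unknown imu_mode {self.imu_mode!r}")


@dataclass(frozen=True)
class _Harmonic:
    axis: int          # 0=AP, 1=ML, 2=vertical
    amp: float         # metres
    mult: int          # multiple of the stride frequency
    phase: float       # radians
    protected: bool = False  # phase locked to event timing; never jittered


@dataclass(frozen=True)
class _MarkerSpec:
    name: str
    base: tuple[float, float, float]
    harmonics: tuple[_Harmonic, ...]


def _h(axis, amp, mult, phase, protected=False):
    return _Harmonic(axis, amp, mult, phase, protected)


def _central(zphase_off=0.0, zamp=0.02, xamp=0.010, yamp=0.020):
    return (
        _h(0, xamp, 2, 0.4),
        _h(1, yamp, 1, 0.0),
        _h(2, zamp, 2, PHASE_VERTICAL + zphase_off, protected=zphase_off == 0.0),
    )


def _base_marker_specs() -> tuple[_MarkerSpec, ...]:
    """Right-side template; left markers are built by a half-stride time shift."""
    specs: list[_MarkerSpec] = [
        _MarkerSpec("HEAD_TOP", (0.0, 0.0, 1.72), (
            _h(0, 0.008, 2, 0.6), _h(1, 0.015, 1, 0.3), _h(2, 0.018, 2, PHASE_VERTICAL + 0.2),
        )),
        _MarkerSpec("C7", (0.0, 0.0, 1.45), (
            _h(0, 0.009, 2, 0.5), _h(1, 0.016, 1, 0.2), _h(2, 0.019, 2, PHASE_VERTICAL + 0.15),
        )),
        _MarkerSpec("SACRUM", (-0.10, 0.0, 1.02), _central()),
        _MarkerSpec("L_ASIS", (0.08, 0.13, 1.00), _central()),
        _MarkerSpec("R_ASIS", (0.08, -0.13, 1.00), _central()),
    ]
    # bilateral markers: (name stem, base for the right side, harmonics for the
    # right side); the left side mirrors y and shifts time by half a stride.
    arm_swing = math.pi  # arms swing in antiphase with the ipsilateral leg
    bilateral = [
        ("SHOULDER", (0.0, -0.20, 1.40), (
            _h(0, 0.012, 1, arm_swing), _h(0, 0.010, 2, 0.4),
            _h(1, 0.018, 1, 0.1), _h(2, 0.020, 2, PHASE_VERTICAL + 0.1),
        )),
        ("ELBOW", (0.0, -0.23, 1.15), (
            _h(0, 0.050, 1, arm_swing), _h(0, 0.010, 2, 0.2),
            _h(1, 0.020, 1, 0.0), _h(2, 0.015, 2, PHASE_VERTICAL + 0.3),
            _h(2, 0.010, 1, arm_swing + 0.5),
        )),
        ("WRIST", (0.0, -0.25, 0.90), (
            _h(0, 0.090, 1, arm_swing), _h(0, 0.012, 2, 0.3),
            _h(1, 0.022, 1, 0.0), _h(2, 0.030, 1, arm_swing + 0.8),
            _h(2, 0.012, 2, PHASE_VERTICAL + 0.4),
        )),
        ("HIP", (0.0, -0.09, 0.92), (
            _h(0, 0.012, 2, 0.4), _h(1, 0.020, 1, 0.0),
            _h(2, 0.020, 2, PHASE_VERTICAL),
        )),
        ("KNEE", (0.0, -0.10, 0.50), (
            _h(0, 0.120, 1, 0.0), _h(0, 0.015, 2, 0.9),
            _h(1, 0.015, 1, 0.0), _h(2, 0.025, 1, 0.5),
            _h(2, 0.012, 2, PHASE_VERTICAL + 0.5),
        )),
        ("ANKLE", (0.0, -0.11, 0.09), (
            _h(0, 0.240, 1, 0.0), _h(0, 0.020, 2, 1.1),
            _h(1, 0.015, 1, 0.0), _h(2, 0.040, 1, 1.2),
            _h(2, 0.015, 2, PHASE_VERTICAL + 0.8),
        )),
        ("HEEL", (-0.05, -0.11, 0.05), (
            _h(0, 0.230, 1, 0.0), _h(1, 0.015, 1, 0.0),
            _h(2, 0.035, 1, PHASE_HEEL, protected=True),
        )),
        ("TOE", (0.15, -0.11, 0.03), (
            _h(0, 0.270, 1, 0.0), _h(0, 0.020, 2, 1.0),
            _h(1, 0.015, 1, 0.0), _h(2, 0.045, 1, 1.0),
            _h(2, 0.010, 2, PHASE_VERTICAL + 0.7),
        )),
    ]
    for stem, base, harmonics in bilateral:
        specs.append(_MarkerSpec(f"R_{stem}", base, harmonics))
        left_base = (base[0], -base[1], base[2])
        left_h = tuple(
            replace(h, phase=h.phase + h.mult * math.pi) for h in harmonics
        )
        specs.append(_MarkerSpec(f"L_{stem}", left_base, left_h))
    return tuple(specs)


_TEMPLATE = _base_marker_specs()

#: pelvis-segment CoM weights over pelvis markers (proximal centroid of the
#: two ASIS markers, CoM halfway towards the sacrum)
PELVIS_WEIGHTS = {"L_ASIS": 0.25, "R_ASIS": 0.25, "SACRUM": 0.5}


def _subject_rng(config: GaitSimConfig, subject_index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed & 0x7FFFFFFF, subject_index, stream])


def _subject_specs(config: GaitSimConfig, subject_index: int):
    """Per-subject stride duration and jittered marker templates (deterministic)."""
    rng = _subject_rng(config, subject_index, 0)
    z = rng.standard_normal()
    z = float(np.clip(z, -3.0, 3.0))
    stride_T = config.stride_duration + config.stride_duration_sd * z
    if config.rigid_body:
        common = _central()
        specs = tuple(_MarkerSpec(s.name, s.base, common) for s in _TEMPLATE)
        return stride_T, specs
    specs = []
    for spec in _TEMPLATE:
        harmonics = []
        for h in spec.harmonics:
            factor = float(np.clip(1.0 + config.amp_jitter * rng.standard_normal(), 0.5, 1.5))
            dphase = 0.0 if h.protected else config.phase_jitter * rng.standard_normal()
            harmonics.append(
                replace(h, amp=h.amp * factor * config.oscillation_scale, phase=h.phase + dphase)
            )
        specs.append(_MarkerSpec(spec.name, spec.base, tuple(harmonics)))
    return stride_T, tuple(specs)


def _trial_duration(config: GaitSimConfig, stride_T: float) -> float:
    return (config.n_strides + TRIAL_MARGIN_STRIDES) * stride_T


def _positions(spec: _MarkerSpec, t: np.ndarray, omega: float, speed: float) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    pos = np.tile(np.asarray(spec.base), (t.size, 1))
    pos[:, 0] += speed * t
    for h in spec.harmonics:
        pos[:, h.axis] += h.amp * np.sin(h.mult * omega * t + h.phase)
    return pos


def _accelerations(weights: dict[str, float], specs, t: np.ndarray, omega: float) -> np.ndarray:
    """Analytic second derivative of a weighted marker combination."""
    t = np.asarray(t, dtype=float)
    acc = np.zeros((t.size, 3))
    by_name = {s.name: s for s in specs}
    for name, w in weights.items():
        for h in by_name[name].harmonics:
            acc[:, h.axis] -= w * h.amp * (h.mult * omega) ** 2 * np.sin(
                h.mult * omega * t + h.phase
            )
    return acc


def _yaw_matrix(angle_deg: float) -> np.ndarray:
    a = math.radians(angle_deg)
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, s, 0.0], [-s, c, 0.0], [0.0, 0.0, 1.0]])


@dataclass
class SyntheticTrial:
    subject_id: str
    markers: MarkerFrameSeries
    imu: UniformSeries                # (n, 3) m/s^2, gravity on z, sensor frame
    truth_com: ComTrajectory          # noise-free whole-body CoM at marker rate
    truth_hs: np.ndarray              # right-foot heel-strike times, s
    stride_duration: float            # realized stride time for this subject
    config: GaitSimConfig = field(repr=False)


def _heel_minima(stride_T: float, duration: float, rigid: bool) -> np.ndarray:
    """Analytic minima of the tracked (right) heel height within the trial."""
    if rigid:
        # height follows the central double-frequency harmonic: minima where
        # sin(2*w*t + PHASE_VERTICAL) = -1  ->  t = (0.4 + k/2) * T
        first, step = 0.4 * stride_T, 0.5 * stride_T
    else:
        first, step = HS_PHASE_FRAC * stride_T, stride_T
    times = np.arange(first, duration, step)
    return times[times < duration]


def generate_trial(config: GaitSimConfig, subject_index: int = 0) -> SyntheticTrial:
    """Generate one subject's walking trial (markers + virtual L5 IMU + truth)."""
    stride_T, specs = _subject_specs(config, subject_index)
    omega = TWO_PI / stride_T
    duration = _trial_duration(config, stride_T)

    n_frames = int(math.floor(duration * config.marker_rate))
    t_m = np.arange(n_frames) / config.marker_rate
    noise_rng = _subject_rng(config, subject_index, 1)

    positions = {}
    clean = {}
    for spec in specs:
        p = _positions(spec, t_m, omega, config.walking_speed)
        clean[spec.name] = p
        positions[spec.name] = p + noise_rng.normal(0.0, config.marker_noise_sd, p.shape)

    # the ML5 marker sits on the IMU: pelvis CoM displaced by the sensor offset
    pelvis = sum(w * clean[name] for name, w in PELVIS_WEIGHTS.items())
    ml5 = pelvis + np.asarray(config.sensor_offset)
    positions["ML5"] = ml5 + noise_rng.normal(0.0, config.marker_noise_sd, ml5.shape)
    clean["ML5"] = ml5

    markers = MarkerFrameSeries(rate=config.marker_rate, positions=positions)

    model = default_body_model()
    clean_series = MarkerFrameSeries(rate=config.marker_rate, positions=clean)
    from .body_model import whole_body_com  # local import to avoid cycle at module load

    truth_com = whole_body_com(model, clean_series)

    n_imu = int(math.floor(duration * config.imu_rate))
    t_i = np.arange(n_imu) / config.imu_rate
    if config.imu_mode == "analytic":
        acc_world = _accelerations(PELVIS_WEIGHTS, specs, t_i, omega)
    else:
        # numerically differentiated pelvis-CoM positions, same algorithm the
        # camera-side pipeline uses (closure harness)
        pelvis_i = sum(
            w * _positions({s.name: s for s in specs}[name], t_i, omega, config.walking_speed)
            for name, w in PELVIS_WEIGHTS.items()
        )
        from .signal_processing import finite_difference

        acc_world = finite_difference(
            UniformSeries(config.imu_rate, pelvis_i, unit="m"), deriv_order=2
        ).values
    acc_sensor = acc_world @ _yaw_matrix(config.axis_misalignment_deg).T
    acc_sensor[:, 2] += config.gravity
    acc_sensor = acc_sensor + noise_rng.normal(0.0, config.imu_noise_sd, acc_sensor.shape)
    imu = UniformSeries(config.imu_rate, acc_sensor, unit="m/s^2")

    truth_hs = _heel_minima(stride_T, duration, config.rigid_body)
    return SyntheticTrial(
        subject_id=f"S{subject_index + 1:02d}",
        markers=markers,
        imu=imu,
        truth_com=truth_com,
        truth_hs=truth_hs,
        stride_duration=stride_T,
        config=config,
    )


def generate_cohort(config: GaitSimConfig) -> list[SyntheticTrial]:
    """One trial per subject; subject seeds derive deterministically from config.seed."""
    return [generate_trial(config, i) for i in range(config.n_subjects)]


def analytic_com(config: GaitSimConfig, t, subject_index: int = 0) -> np.ndarray:
    """Exact whole-body CoM of the noise-free generator at arbitrary times.

    Independent of any sampling grid; raises :class:`DomainError` for times
    outside the trial span.
    """
    stride_T, specs = _subject_specs(config, subject_index)
    duration = _trial_duration(config, stride_T)
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0) or np.any(t_arr > duration):
        raise DomainError(f"time outside trial span [0, {duration:.3f}] s")
    omega = TWO_PI / stride_T
    model = default_body_model()
    by_name = {s.name: s for s in specs}
    com = np.zeros((t_arr.size, 3))
    for seg in model.segments:
        prox = np.mean(
            [_positions(by_name[m], t_arr, omega, config.walking_speed) for m in seg.proximal_markers],
            axis=0,
        )
        dist = np.mean(
            [_positions(by_name[m], t_arr, omega, config.walking_speed) for m in seg.distal_markers],
            axis=0,
        )
        com += seg.mass_fraction * (prox + seg.com_ratio * (dist - prox))
    return com[0] if np.isscalar(t) or np.ndim(t) == 0 else com


def analytic_pelvis_acceleration(config: GaitSimConfig, t, subject_index: int = 0) -> np.ndarray:
    """Exact world-frame pelvis-CoM acceleration (no gravity, no misalignment)."""
    stride_T, specs = _subject_specs(config, subject_index)
    omega = TWO_PI / stride_T
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    acc = _accelerations(PELVIS_WEIGHTS, specs, t_arr, omega)
    return acc[0] if np.ndim(t) == 0 else acc
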