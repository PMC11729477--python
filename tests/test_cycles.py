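"""Cycle segmentation, 101-node resampling, amplitude normalization and
ensemble statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gaitcom.cycles import (N_NODES, NormalizedCycleSet, amplitude_normalize,
                            ensemble_average, segment_cycles, time_normalize)
from gaitcom.errors import DataError
from gaitcom.gait_events import EventSeries, detect_hs_camera
from gaitcom.signal_processing import UniformSeries


def _series(rate=240.0, duration=6.0, fn=np.sin):
    t = np.arange(int(duration * rate)) / rate
    return UniformSeries(rate, fn(t), "m/s^2"), t


def test_segmentation_counts_with_edge_trim():
    series, _ = _series()
    events = EventSeries(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), "camera")
    raw = segment_cycles(series, events, trim_edges=False)
    trimmed = segment_cycles(series, events)
    assert len(raw) == 4
    assert len(trimmed) == 2
    assert trimmed[0].t_start == pytest.approx(2.0)


def test_two_events_keep_single_cycle_with_warning():
    series, _ = _series()
    events = EventSeries(np.array([1.0, 2.0]), "camera")
    with pytest.warns(UserWarning, match="no trim"):
        cycles = segment_cycles(series, events)
    assert len(cycles) == 1


def test_segmentation_requires_two_events():
    series, _ = _series()
    with pytest.raises(DataError):
        segment_cycles(series, EventSeries(np.array([1.0]), "camera"))


def test_cycle_durations_recover_stride_time(clean_trial):
    heel_z = UniformSeries(clean_trial.markers.rate,
                           clean_trial.markers.positions["R_HEEL"][:, 2], "m")
    events = detect_hs_camera(heel_height=heel_z)
    series = UniformSeries(clean_trial.markers.rate,
                           clean_trial.markers.positions["SACRUM"], "m")
    cycles = segment_cycles(series, events)
    durations = np.array([c.duration for c in cycles])
    assert np.allclose(durations, clean_trial.stride_duration, atol=0.01)


def test_time_normalize_constant_and_linear():
    series, t = _series(fn=lambda t: np.full_like(t, 2.5))
    events = EventSeries(np.array([1.0, 2.0, 3.0, 4.0]), "camera")
    cyc = segment_cycles(series, events)[0]
    out = time_normalize(cyc)
    assert out.shape == (N_NODES,)
    assert np.allclose(out, 2.5, atol=1e-12)

    series, t = _series(fn=lambda t: 3.0 * t - 1.0)
    cyc = segment_cycles(series, events)[0]
    out = time_normalize(cyc)
    a = 3.0 * cyc.t_start - 1.0
    b = 3.0 * cyc.t_end - 1.0
    expected = a + (b - a) * np.linspace(0, 1, N_NODES)
    assert np.max(np.abs(out - expected)) < 1e-9


def test_time_normalize_sinusoid_against_closed_form():
    series, t = _series(fn=lambda t: np.sin(2 * np.pi * t))
    events = EventSeries(np.array([1.0, 2.0, 3.0, 4.0]), "camera")
    cyc = segment_cycles(series, events)[0]
    out = time_normalize(cyc)
    nodes = cyc.t_start + np.linspace(0, 1, N_NODES) * cyc.duration
    assert np.max(np.abs(out - np.sin(2 * np.pi * nodes))) < 1e-4


def test_time_normalize_rate_invariance_for_bandlimited_input():
    events = EventSeries(np.array([1.0, 2.1, 3.2, 4.3]), "camera")
    outs = []
    for rate in (240.0, 480.0):
        t = np.arange(int(6.0 * rate)) / rate
        series = UniformSeries(rate, np.sin(2 * np.pi * 1.3 * t + 0.4), "m/s^2")
        cyc = segment_cycles(series, events)[0]
        outs.append(time_normalize(cyc))
    assert np.max(np.abs(outs[0] - outs[1])) < 1e-6


@pytest.mark.parametrize(
    "curve, divisor",
    [(np.array([4.0, -2.0, 1.0]), 4.0), (np.array([2.0, -6.0, 0.0]), 6.0)],
)
def test_amplitude_normalize_scales_by_largest_excursion(curve, divisor):
    out = amplitude_normalize(curve)
    assert np.allclose(out, curve / divisor, atol=1e-12)
    assert out.min() >= -1.0 and out.max() <= 1.0
    assert np.isclose(np.abs(out), 1.0).any()


@settings(max_examples=50, deadline=None)
@given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=30).filter(
    lambda v: max(abs(x) for x in v) > 0))
def test_amplitude_normalize_idempotent(values):
    curve = np.asarray(values)
    once = amplitude_normalize(curve)
    twice = amplitude_normalize(once)
    assert np.allclose(once, twice, atol=1e-12)


def test_amplitude_normalize_zero_curve_warns():
    with pytest.warns(UserWarning):
        out = amplitude_normalize(np.zeros(5))
    assert np.array_equal(out, np.zeros(5))


def test_ensemble_average_basics():
    c = np.linspace(-1, 1, N_NODES)
    mean, sd = ensemble_average([c, c, c])
    assert np.allclose(mean, c) and np.allclose(sd, 0.0)
    mean, _ = ensemble_average([c, -c])
    assert np.allclose(mean, 0.0, atol=1e-12)
    with pytest.raises(DataError):
        ensemble_average([])


def test_ensemble_sd_recovers_noise_sigma(rng):
    base = np.sin(np.linspace(0, 2 * np.pi, N_NODES))
    sigma = 0.37
    cycles = base + rng.normal(0.0, sigma, size=(1000, N_NODES))
    _, sd = ensemble_average(cycles)
    assert np.all(np.abs(sd - sigma) < 0.05 * sigma * 5)
    assert abs(sd.mean() - sigma) < 0.05 * sigma


def test_cycle_set_shape_and_pooled_count(rng):
    data = rng.normal(size=(16, 3, N_NODES, 3))
    cs = NormalizedCycleSet(data, tuple(f"S{i:02d}" for i in range(16)))
    assert cs.condition("IMU").size == 16 * N_NODES * 3
    norm = cs.amplitude_normalized()
    assert norm.data.max() <= 1.0 and norm.data.min() >= -1.0


def test_cycle_set_long_roundtrip(rng):
    data = rng.normal(size=(3, 3, N_NODES, 3))
    cs = NormalizedCycleSet(data, ("S01", "S02", "S03"))
    frame = cs.to_long()
    back = NormalizedCycleSet.from_long(frame)
    assert np.allclose(back.data, cs.data)
    assert back.subjects == cs.subjects
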