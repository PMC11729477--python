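"""Filtering and differentiation contracts: zero phase, unit passband gain,
analytic transfer-function magnitudes, and stencil exactness."""

import numpy as np
import pytest
from scipy import signal as sig

from gaitcom.errors import DataError, FilterSpecError
from gaitcom.signal_processing import (FilterSpec, UniformSeries,
                                       butterworth_zero_lag, finite_difference,
                                       gravity_correct)


def _sine(freq, rate, duration, amp=1.0, phase=0.0):
    t = np.arange(int(duration * rate)) / rate
    return t, amp * np.sin(2 * np.pi * freq * t + phase)


def test_deep_passband_sinusoid_preserved():
    t, x = _sine(1.0, 240.0, 10.0)
    spec = FilterSpec(order=4, cutoff=12.0, rate=240.0)
    y = butterworth_zero_lag(UniformSeries(240.0, x, "m"), spec).values
    interior = slice(240, -240)
    amp = np.sqrt(2.0 * np.mean(y[interior] ** 2))
    assert 0.999 <= amp <= 1.001
    lags = sig.correlation_lags(len(x[interior]), len(y[interior]))
    xc = sig.correlate(x[interior], y[interior])
    assert lags[np.argmax(xc)] == 0


def test_constant_series_passes_unchanged():
    spec = FilterSpec(order=4, cutoff=12.0, rate=240.0)
    x = np.full(2000, 3.7)
    y = butterworth_zero_lag(UniformSeries(240.0, x, "m"), spec).values
    assert np.allclose(y, 3.7, atol=1e-9)


def test_cutoff_attenuation_matches_designed_transfer_function():
    """The zero-lag pass applies |H(f)|^2 of the underlying design; at the
    cutoff of a Butterworth that is exactly half power -> amplitude 0.5."""
    rate, cutoff = 240.0, 12.0
    spec = FilterSpec(order=4, cutoff=cutoff, rate=rate)
    sos = sig.butter(spec.design_order, cutoff, btype="low", fs=rate, output="sos")
    _, h = sig.sosfreqz(sos, worN=[cutoff], fs=rate)
    expected_gain = np.abs(h[0]) ** 2
    t, x = _sine(cutoff, rate, 30.0)
    y = butterworth_zero_lag(UniformSeries(rate, x, "m"), spec).values
    interior = slice(int(2 * rate), -int(2 * rate))
    amp = np.sqrt(2.0 * np.mean(y[interior] ** 2))
    assert amp == pytest.approx(expected_gain, rel=5e-3)
    assert expected_gain == pytest.approx(0.5, abs=1e-6)


def test_filter_spec_validation():
    with pytest.raises(FilterSpecError):
        FilterSpec(order=4, cutoff=130.0, rate=240.0)  # >= Nyquist
    with pytest.raises(FilterSpecError):
        FilterSpec(order=3, cutoff=12.0, rate=240.0)  # odd effective order
    with pytest.raises(DataError):
        butterworth_zero_lag(UniformSeries(240.0, np.zeros(5), "m"),
                             FilterSpec(order=4, cutoff=12.0, rate=240.0))


def test_second_difference_exact_on_quadratics():
    t = np.arange(100) / 37.0
    series = UniformSeries(37.0, t ** 2, "m")
    acc = finite_difference(series, deriv_order=2).values
    assert np.max(np.abs(acc[1:-1] - 2.0)) < 1e-9


def test_first_difference_exact_on_ramps_including_endpoints():
    t = np.arange(50) / 10.0
    vel = finite_difference(UniformSeries(10.0, 3.0 * t - 1.0, "m"), 1).values
    assert np.max(np.abs(vel - 3.0)) < 1e-9


def test_second_derivative_of_sinusoid_within_truncation_bound():
    rate = 240.0
    t, x = _sine(1.0, rate, 5.0)
    acc = finite_difference(UniformSeries(rate, x, "m"), 2).values
    expected = -(2 * np.pi) ** 2 * np.sin(2 * np.pi * t)
    # central-difference truncation: |f''''| * dt^2 / 12
    bound = (2 * np.pi) ** 4 / rate ** 2 / 12.0
    assert np.max(np.abs(acc[1:-1] - expected[1:-1])) < 2.0 * bound


def test_repeated_first_difference_approximates_second():
    rate = 240.0
    t, x = _sine(2.0, rate, 3.0)
    once = finite_difference(UniformSeries(rate, x, "m"), 1)
    twice = finite_difference(once, 1).values
    direct = finite_difference(UniformSeries(rate, x, "m"), 2).values
    bound = 10.0 * (2 * np.pi * 2) ** 4 / rate ** 2
    assert np.max(np.abs(twice[2:-2] - direct[2:-2])) < bound


def test_differentiator_linearity(rng):
    x = rng.normal(size=200)
    y = rng.normal(size=200)
    a, b = 2.5, -1.3
    for order in (1, 2):
        fx = finite_difference(UniformSeries(100.0, x, "m"), order).values
        fy = finite_difference(UniformSeries(100.0, y, "m"), order).values
        fab = finite_difference(UniformSeries(100.0, a * x + b * y, "m"), order).values
        assert np.allclose(fab, a * fx + b * fy, rtol=1e-9, atol=1e-9)


def test_filter_linearity(rng):
    spec = FilterSpec(order=4, cutoff=12.0, rate=240.0)
    x = rng.normal(size=1000)
    y = rng.normal(size=1000)
    fx = butterworth_zero_lag(UniformSeries(240.0, x, "m"), spec).values
    fy = butterworth_zero_lag(UniformSeries(240.0, y, "m"), spec).values
    fab = butterworth_zero_lag(UniformSeries(240.0, 2 * x - 3 * y, "m"), spec).values
    assert np.allclose(fab, 2 * fx - 3 * fy, rtol=1e-9, atol=1e-9)


def test_zero_lag_group_delay_is_zero_on_bandlimited_signal(rng):
    rate = 240.0
    t = np.arange(int(20 * rate)) / rate
    x = sum(np.sin(2 * np.pi * f * t + p) for f, p in [(1.1, 0.3), (2.7, 1.1), (4.3, 2.0)])
    spec = FilterSpec(order=4, cutoff=12.0, rate=rate)
    y = butterworth_zero_lag(UniformSeries(rate, x, "m"), spec).values
    interior = slice(int(2 * rate), -int(2 * rate))
    lags = sig.correlation_lags(len(x[interior]), len(y[interior]))
    xc = sig.correlate(x[interior], y[interior])
    assert lags[np.argmax(xc)] == 0


@pytest.mark.parametrize(
    "reading, expected",
    [
        ((0.0, 0.0, 9.81), (0.0, 0.0, 0.0)),
        ((0.3, -0.1, 9.81), (0.3, -0.1, 0.0)),
    ],
)
def test_gravity_correction(reading, expected):
    series = UniformSeries(128.0, np.tile(reading, (10, 1)), "m/s^2")
    out = gravity_correct(series, g=9.81).values
    assert np.allclose(out, np.tile(expected, (10, 1)), atol=1e-12)


def test_gravity_corrected_synthetic_vertical_mean_is_zero():
    from gaitcom.synthetic import GaitSimConfig, generate_trial

    cfg = GaitSimConfig(n_subjects=1, n_strides=10, stride_duration=1.0,
                        stride_duration_sd=0.0, marker_noise_sd=0.0,
                        imu_noise_sd=0.0, seed=11)
    trial = generate_trial(cfg, 0)
    n = int(round(8 * trial.stride_duration * cfg.imu_rate))
    corrected = gravity_correct(trial.imu, g=cfg.gravity)
    assert abs(corrected.values[:n, 2].mean()) < 1e-6
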