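import numpy as np
import pytest

from gaitcom.synthetic import GaitSimConfig, generate_trial


@pytest.fixture(scope="session")
def clean_config():
    """Noise-free, perfectly aligned sensor: every identity should be exact."""
    return GaitSimConfig(
        n_subjects=1,
        n_strides=10,
        stride_duration=1.1,
        stride_duration_sd=0.0,
        marker_noise_sd=0.0,
        imu_noise_sd=0.0,
        sensor_offset=(0.0, 0.0, 0.0),
        axis_misalignment_deg=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def clean_trial(clean_config):
    return generate_trial(clean_config, 0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
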