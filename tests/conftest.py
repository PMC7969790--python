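import numpy as np
import pytest

from gaitrel import HorseKinematicProfile, SessionProtocol, simulate_session


@pytest.fixture(scope="session")
def default_profile():
    return HorseKinematicProfile()


@pytest.fixture(scope="session")
def clean_session(default_profile):
    """Noise-free default session (walk + ramps + 25 trot strides)."""
    protocol = SessionProtocol(noise_sd_gyro=0.0, noise_sd_accel=0.0, seed=1)
    return simulate_session(default_profile, protocol)


@pytest.fixture(scope="session")
def pure_trot_session(default_profile):
    """Noise-free session with only standstill + 20 steady trot strides."""
    protocol = SessionProtocol(
        n_trot_strides=20,
        walk_segments=(),
        ramp_strides=0,
        noise_sd_gyro=0.0,
        noise_sd_accel=0.0,
        seed=2,
    )
    return simulate_session(default_profile, protocol)


def circular_distance(a, b):
    """Distance between two cycle percentages on the 0-100 circle."""
    d = abs((a - b) % 100.0)
    return min(d, 100.0 - d)


@pytest.fixture(scope="session")
def circ():
    return circular_distance
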