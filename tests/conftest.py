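import numpy as np
import pytest

from hippocan import Arena, StripePlate, generate_random_walk, relax_to_pattern
from hippocan.stripe import calibrate_displacement_gain


@pytest.fixture(scope="session")
def formed_plate():
    """A default 120-cell plate with its stripe pattern formed (seed 0)."""
    plate = StripePlate()
    relax_to_pattern(plate, seed=0)
    # let the freshly formed pattern finish settling (zero velocity)
    from hippocan.stripe import step_dynamics

    for _ in range(2000):
        step_dynamics(plate, np.zeros(2), 0.001)
    return plate


@pytest.fixture(scope="session")
def calibrated_plate(formed_plate):
    """Plate with a displacement gain calibrated on a 1 m x 1 m roam.

    Session-scoped: the calibration roam is the expensive part of the stripe
    tests and its result is reused read-only (copies are taken by tests that
    mutate state).
    """
    plate = formed_plate.copy()
    traj = generate_random_walk(Arena(1.0, 1.0), 60.0, 0.1, seed=11)
    result = calibrate_displacement_gain(plate, traj)
    return plate, result


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
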