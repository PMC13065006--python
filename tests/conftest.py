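import numpy as np
import pytest

from mechwork.body_model import (
    default_segment_lengths,
    load_segment_table,
    scale_segment_parameters,
)
from mechwork.simulate import PlayerParams, default_camera_rig, simulate_trial


@pytest.fixture(scope="session")
def male_table():
    return load_segment_table("male")


@pytest.fixture(scope="session")
def scaled_male(male_table):
    return scale_segment_parameters(77.2, default_segment_lengths(1.82), male_table)


@pytest.fixture(scope="session")
def male_player(scaled_male):
    return PlayerParams(
        player_id="P01", sex="male", body_mass=77.2, height=1.82,
        baseline_velocity=6.0, slope=5e-4, cycle_work_estimate=240.0,
        scaled_segments=scaled_male,
    )


@pytest.fixture(scope="session")
def camera_rig():
    return default_camera_rig()


@pytest.fixture(scope="session")
def noiseless_trial(male_player):
    """One deterministic skeleton trial with ground truth (shared, read-only)."""
    return simulate_trial(male_player, 1, seed=42, noise=False)


@pytest.fixture(scope="session")
def noisy_trial(male_player, camera_rig):
    """One realistic trial with bounding boxes (shared, read-only)."""
    return simulate_trial(male_player, 1, seed=42, cameras=camera_rig)


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)
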