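import numpy as np
import pytest

from bruisepose.knee_frames import pose_from_parameters
from bruisepose.synthetic_knee import (
    BruiseStampParams,
    KneeGeometryParams,
    SquatModelParams,
    generate_knee,
    simulate_squat,
    stamp_bruises,
)


@pytest.fixture(scope="session")
def default_knee():
    """One surrogate knee at default geometry (shared, treated as read-only)."""
    return generate_knee(KneeGeometryParams())


@pytest.fixture(scope="session")
def injury_pose():
    """A bicompartmental-contact injury pose for the default geometry."""
    return pose_from_parameters(flexion=46.0, vv=2.0, ie=-6.0, ap=46.0, pd=-3.0)


@pytest.fixture(scope="session")
def stamped(default_knee, injury_pose):
    """Noiseless bruise patches stamped under the known pose."""
    femur, tibia = default_knee
    patches = stamp_bruises(femur, tibia, injury_pose, BruiseStampParams(seed=0))
    return femur, tibia, patches


@pytest.fixture(scope="session")
def noiseless_squat():
    return simulate_squat(SquatModelParams(noise_sd_mm=0.0, noise_sd_deg=0.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)
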