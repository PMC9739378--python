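import numpy as np
import pytest

from gaitblur import GaitConfig, generate_camera_rig, generate_gait_sequence


@pytest.fixture(scope="session")
def short_gait():
    """Two gait cycles at 60 Hz with default adult anthropometry."""
    return generate_gait_sequence(GaitConfig(n_cycles=2))


@pytest.fixture(scope="session")
def neutral_pose():
    """A static standing pose (all profile amplitudes zero, no translation)."""
    cfg = GaitConfig(
        n_cycles=1, walking_speed=0.0,
        hip_flexion_amp=0.0, knee_flexion_amp=0.0, ankle_flexion_amp=0.0,
        arm_swing_amp=0.0, elbow_amp=0.0, neck_flexion_amp=0.0,
        pelvis_roll_amp=0.0,
    )
    return generate_gait_sequence(cfg)


@pytest.fixture(scope="session")
def rig():
    return generate_camera_rig(n_cameras=4, radius=3000.0, height=1200.0,
                               image_size=(640, 480), focal_px=600.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_rotation(rng):
    """Uniform random rotation matrix (QR of a Gaussian matrix, det fixed)."""
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q
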