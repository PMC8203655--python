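import numpy as np
import pytest
from scipy.spatial.transform import Rotation


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_unit_quats(rng, n):
    """Uniform random unit quaternions, scalar-first."""
    q = rng.normal(size=(n, 4))
    return q / np.linalg.norm(q, axis=1, keepdims=True)


def smooth_orientation_path(rng, n, dt=0.005, rate=1.0):
    """C∞ orientation path: integrates a slowly varying angular velocity."""
    t = np.arange(n) * dt
    omega = np.column_stack([
        rate * np.sin(2 * np.pi * 0.5 * t + phase)
        for phase in rng.uniform(0, 2 * np.pi, 3)
    ])
    rots = [Rotation.identity()]
    for i in range(1, n):
        rots.append(rots[-1] * Rotation.from_rotvec(omega[i - 1] * dt))
    q = np.array([r.as_quat(scalar_first=True) for r in rots])
    return t, q, omega


@pytest.fixture
def pose_factory(rng):
    from headtrack.io_model import PoseTrajectory

    def make(n=100, dt=0.02, frame_id="W"):
        t = np.arange(n) * dt
        p = np.cumsum(rng.normal(0, 0.01, (n, 3)), axis=0)
        q = random_unit_quats(rng, n)
        return PoseTrajectory(t, p, q, frame_id)

    return make
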