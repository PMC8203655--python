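import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from headtrack import alignment, quat
from headtrack.alignment import (
    DegenerateGeometryError,
    DegenerateSignalError,
    FrameTransform,
    FrameTree,
    InsufficientOverlapError,
)
from headtrack.io_model import ImuTrajectory, KinematicTrajectory, PoseTrajectory
from headtrack.synthetic import SimulationConfig, simulate_truth
from headtrack.kinematics import derive_kinematics

from conftest import smooth_orientation_path


@pytest.fixture(scope="module")
def nod_shake_norms():
    """Angular-velocity norm of a simulated nod/shake segment, 50 Hz grid."""
    truth, sync_end = simulate_truth(SimulationConfig())
    kin = derive_kinematics(truth.slice_time(0.0, sync_end))
    norm = np.linalg.norm(kin.omega, axis=1)
    return kin.t[::4], norm[::4]   # 50 Hz


class TestTimeOffset:
    def test_identical_series_give_zero(self, nod_shake_norms):
        t, x = nod_shake_norms
        res = alignment.estimate_time_offset((t, x), (t, x))
        assert res.delta_t == pytest.approx(0.0, abs=1e-12)
        assert res.lag_index == int(np.argmax(res.correlation_profile[:, 1]))

    @pytest.mark.parametrize("offset", [-1.3, 0.37, 2.0])
    def test_constructed_shift_recovered_within_one_sample(self, nod_shake_norms, offset):
        t, x = nod_shake_norms
        res = alignment.estimate_time_offset((t + offset, x), (t, x))
        assert abs(res.delta_t - offset) <= 1.0 / 50.0 + 1e-9

    def test_noisy_shift_recovered_within_two_samples(self, nod_shake_norms):
        t, x = nod_shake_norms
        sd = np.sqrt(np.var(x) / 10.0)   # SNR 10
        rng = np.random.default_rng(7)
        for _ in range(25):
            offset = rng.uniform(-2.0, 2.0)
            res = alignment.estimate_time_offset(
                (t + offset, x + rng.normal(0, sd, x.shape)),
                (t, x + rng.normal(0, sd, x.shape)),
            )
            assert abs(res.delta_t - offset) <= 2.0 / 50.0 + 1e-9

    def test_flat_signal_rejected(self):
        t = np.arange(0, 10, 0.02)
        with pytest.raises(DegenerateSignalError):
            alignment.estimate_time_offset((t, np.ones_like(t)), (t, np.ones_like(t)))

    def test_insufficient_overlap_rejected(self, nod_shake_norms):
        t, x = nod_shake_norms
        with pytest.raises(InsufficientOverlapError):
            alignment.estimate_time_offset((t + 100.0, x), (t, x), max_lag=5.0)


class TestTapOffset:
    def _imu(self, tap_time, rate, seed, duration=10.0):
        from headtrack.synthetic import simulate_tap_imu
        return simulate_tap_imu(tap_time, duration, rate, noise_sd=0.05, seed=seed)

    def test_identical_streams_give_zero(self):
        imu = self._imu(1.0, 100.0, 0)
        assert alignment.tap_offset_from_accel(imu, imu) == pytest.approx(0.0, abs=1e-12)

    def test_constructed_taps_recovered(self):
        a = self._imu(1.25, 62.5, 1)
        b = self._imu(1.00, 100.0, 2)
        got = alignment.tap_offset_from_accel(a, b)
        assert got == pytest.approx(0.25, abs=1.0 / 62.5)

    def test_taps_in_noise_recovered_over_replicates(self):
        from headtrack.synthetic import simulate_tap_imu
        rng = np.random.default_rng(5)
        for rep in range(10):
            off = rng.uniform(-0.5, 0.5)
            a = simulate_tap_imu(1.0, 10.0, 100.0, clock_offset=off,
                                 noise_sd=0.5, seed=100 + rep)
            b = simulate_tap_imu(1.0, 10.0, 100.0, noise_sd=0.5, seed=200 + rep)
            got = alignment.tap_offset_from_accel(a, b)
            assert abs(got - off) <= 2.0 / 100.0 + 1e-9

    def test_transient_free_stream_raises(self):
        t = np.arange(0, 10, 0.01)
        imu = ImuTrajectory(t, np.tile([0.0, 0.0, 9.81], (len(t), 1)),
                            np.zeros((len(t), 3)))
        with pytest.raises(DegenerateSignalError):
            alignment.tap_offset_from_accel(imu, imu)


class TestResample:
    def test_identity_on_same_grid(self, rng):
        t, q, _ = smooth_orientation_path(rng, 50, dt=0.02)
        p = rng.normal(size=(50, 3))
        traj = PoseTrajectory(t, p, q)
        out = alignment.resample_to(traj, t)
        np.testing.assert_allclose(out.p, p, atol=1e-12)
        assert np.max(quat.quat_angle_deg(out.q, q)) < 1e-9

    def test_quaternion_norm_preserved(self, rng):
        t, q, _ = smooth_orientation_path(rng, 50, dt=0.05, rate=3.0)
        traj = PoseTrajectory(t, np.zeros((50, 3)), q)
        out = alignment.resample_to(traj, np.sort(rng.uniform(t[0], t[-1], 300)))
        np.testing.assert_allclose(np.linalg.norm(out.q, axis=1), 1.0, atol=1e-9)

    def test_kinematic_resampling_is_linear_interpolation(self, rng):
        t = np.arange(10.0)
        v = np.column_stack([t, 2 * t, -t])
        kin = KinematicTrajectory(t, v, v)
        out = alignment.resample_to(kin, np.array([0.5, 7.25]))
        np.testing.assert_allclose(out.v, [[0.5, 1.0, -0.5], [7.25, 14.5, -7.25]])

    def test_extrapolation_rejected(self, rng):
        t, q, _ = smooth_orientation_path(rng, 10)
        traj = PoseTrajectory(t, np.zeros((10, 3)), q)
        with pytest.raises(Exception, match="span"):
            alignment.resample_to(traj, np.array([t[-1] + 1.0]))


class TestWorldRegistration:
    def test_identity_for_equal_clouds(self, rng):
        p = rng.uniform(-5, 5, (100, 3))
        tr = alignment.register_world_frame(p, p)
        assert quat.quat_angle_deg(tr.rotation, quat.IDENTITY) < 1e-9
        np.testing.assert_allclose(tr.translation, 0.0, atol=1e-9)

    def test_exact_recovery_of_known_transform(self, rng):
        p = rng.uniform(-5, 5, (200, 3))
        r0 = Rotation.random(random_state=3)
        d0 = np.array([1.0, -2.0, 0.5])
        p_hat = (p - d0) @ r0.as_matrix()   # p = R0 p_hat + d0
        tr = alignment.register_world_frame(p_hat, p)
        assert quat.quat_angle_deg(tr.rotation, quat.from_rotation(r0)) < 1e-9
        np.testing.assert_allclose(tr.translation, d0, atol=1e-9)

    def test_rotation_error_under_centimeter_noise(self, rng):
        for rep in range(5):
            p = rng.uniform(-5, 5, (1500, 3))
            r0 = Rotation.random(random_state=100 + rep)
            d0 = rng.uniform(-3, 3, 3)
            p_hat = (p - d0) @ r0.as_matrix() + rng.normal(0, 0.01, (1500, 3))
            tr = alignment.register_world_frame(p_hat, p)
            assert quat.quat_angle_deg(tr.rotation, quat.from_rotation(r0)) < 0.5

    def test_rigidity_preserves_pairwise_distances(self, rng):
        p_hat = rng.uniform(-2, 2, (40, 3))
        p = rng.uniform(-2, 2, (40, 3))
        tr = alignment.register_world_frame(p_hat, p)
        moved = tr.apply_points(p_hat)
        d_before = np.linalg.norm(p_hat[:, None] - p_hat[None, :], axis=-1)
        d_after = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        assert np.max(np.abs(d_before - d_after)) < 1e-9

    def test_collinear_cloud_rejected(self):
        p = np.outer(np.linspace(0, 1, 50), [1.0, 2.0, 3.0])
        with pytest.raises(DegenerateGeometryError):
            alignment.register_world_frame(p, p)


class TestCalibratedFrame:
    def test_already_calibrated_gives_identity(self, rng):
        n = 50
        v = np.tile([1.0, 0, 0], (n, 1)) + rng.normal(0, 1e-9, (n, 3))
        g = np.tile([0, 0, -1.0], (n, 1))
        tr = alignment.estimate_calibrated_frame(v, g)
        assert quat.quat_angle_deg(tr.rotation, quat.IDENTITY) < 1e-6

    @pytest.mark.parametrize("mode", ["instantaneous", "mean"])
    def test_exact_recovery_of_mount_rotation(self, mode):
        r_m = Rotation.from_euler("yx", [20, 10], degrees=True)
        n = 50
        v = np.tile([1.0, 0, 0], (n, 1))
        g = np.tile([0, 0, -1.0], (n, 1))
        # body frame pre-rotated by the mount: coordinates pick up R_m^T
        tr = alignment.estimate_calibrated_frame(v @ r_m.as_matrix(),
                                                 g @ r_m.as_matrix(), mode=mode)
        assert quat.quat_angle_deg(tr.rotation, quat.from_rotation(r_m)) < 1e-6

    def test_recovery_under_heading_jitter(self, rng):
        r_m = Rotation.from_euler("zyx", [15, 20, 10], degrees=True)
        for rep in range(5):
            n = 1000
            jit = Rotation.from_rotvec(np.radians(rng.normal(0, 5, (n, 3))))
            v = jit.apply(np.tile([1.0, 0, 0], (n, 1)))
            g = np.tile([0, 0, -1.0], (n, 1))
            tr = alignment.estimate_calibrated_frame(v @ r_m.as_matrix(),
                                                     g @ r_m.as_matrix())
            assert quat.quat_angle_deg(tr.rotation, quat.from_rotation(r_m)) < 1.5

    def test_heading_parallel_to_gravity_rejected(self):
        n = 20
        v = np.tile([0, 0, -1.0], (n, 1))
        g = np.tile([0, 0, -1.0], (n, 1))
        with pytest.raises(DegenerateGeometryError):
            alignment.estimate_calibrated_frame(v, g)

    def test_gold_aligned_to_device_recovers_relative_rotation(self, rng):
        r = Rotation.from_euler("zyx", [25, -10, 5], degrees=True)
        n = 200
        v_dev = rng.normal(size=(n, 3)) + [3.0, 0, 0]
        g_dev = np.tile([0, 0, -1.0], (n, 1)) + rng.normal(0, 0.05, (n, 3))
        v_gold = v_dev @ r.as_matrix()   # gold frame rotated by r
        g_gold = g_dev @ r.as_matrix()
        tr = alignment.calibrate_gold_to_device(v_gold, g_gold, v_dev, g_dev)
        assert quat.quat_angle_deg(tr.rotation, quat.from_rotation(r)) < 1e-6


class TestFrameTree:
    def test_identity_tree_is_noop(self, pose_factory):
        traj = pose_factory(frame_id="W")
        tree = FrameTree()
        out = alignment.apply_frame_tree(traj, tree, "W")
        np.testing.assert_allclose(out.p, traj.p, atol=1e-12)

    def test_apply_then_inverse_restores(self, pose_factory, rng):
        traj = pose_factory(frame_id="W_hat")
        tr = FrameTransform(quat.from_rotation(Rotation.random(random_state=1)),
                            rng.normal(size=3), "W_hat", "W")
        tree = FrameTree()
        tree.add(tr)
        there = alignment.apply_frame_tree(traj, tree, "W")
        back = alignment.apply_frame_tree(there, tree, "W_hat")
        np.testing.assert_allclose(back.p, traj.p, atol=1e-9)
        assert np.max(quat.quat_angle_deg(back.q, traj.q)) < 1e-9

    def test_two_hop_path_equals_composed_transform(self, rng):
        t1 = FrameTransform(quat.from_rotation(Rotation.random(random_state=2)),
                            rng.normal(size=3), "B_hat", "B")
        t2 = FrameTransform(quat.from_rotation(Rotation.random(random_state=3)),
                            rng.normal(size=3), "B", "C")
        tree = FrameTree()
        tree.add(t1)
        tree.add(t2)
        chained = tree.get("B_hat", "C")
        composed = t2.compose(t1)
        p = rng.normal(size=(20, 3))
        np.testing.assert_allclose(chained.apply_points(p),
                                   composed.apply_points(p), atol=1e-9)

    def test_missing_path_raises(self):
        tree = FrameTree()
        tree.add(FrameTransform(quat.IDENTITY, np.zeros(3), "W_hat", "W"))
        with pytest.raises(KeyError):
            tree.get("W", "C")
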