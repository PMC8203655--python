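"""Temporal synchronization, resampling, and reference-frame calibration.

Three alignment problems arise when comparing a head-worn tracker to a
gold standard:

1. **Time.** The device and gold-standard clocks differ by an unknown
   constant offset. It is recovered from a dedicated synchronization
   segment (slow nodding and shaking of the head) by cross-correlating
   the angular-velocity norms of both streams
   (:func:`estimate_time_offset`), or, where only accelerometers are
   shared, from the transient of tapping the two devices together
   (:func:`tap_offset_from_accel`).

2. **Sampling.** After alignment the device stream is interpolated onto
   the gold-standard timestamps (:func:`resample_to`): linearly for
   positions and velocities, by spherical quadrangle (squad)
   interpolation for orientations.

3. **Frames.** The device world frame Ŵ is registered to the gold
   standard world frame W by rigid (rotation + translation, no scale)
   point-set registration over an estimation window
   (:func:`register_world_frame`). Head-mount placement is removed by
   rotating each body frame into a *calibrated* frame whose x axis is
   the mean locomotion direction and whose z axis opposes gravity
   (:func:`estimate_calibrated_frame`,
   :func:`calibrate_gold_to_device`), solved as least-squares attitude
   (Wahba) problems with determinant-corrected SVD.

Scale is deliberately *not* estimated in the world registration: scale
error of the device is itself a measured outcome (trajectory length and
speed errors) and absorbing it here would mask it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import quat
from .io_model import (
    ImuTrajectory,
    KinematicTrajectory,
    PoseTrajectory,
    ValidationError,
)

__all__ = [
    "SyncResult",
    "FrameTransform",
    "FrameTree",
    "estimate_time_offset",
    "tap_offset_from_accel",
    "resample_to",
    "register_world_frame",
    "solve_attitude",
    "estimate_calibrated_frame",
    "calibrate_gold_to_device",
    "apply_frame_tree",
]


class InsufficientOverlapError(ValueError):
    pass


class DegenerateSignalError(ValueError):
    pass


class DegenerateGeometryError(ValueError):
    pass


@dataclass
class SyncResult:
    """Estimated clock offset between a device and a gold-standard stream.

    Shifting the device timestamps by ``-delta_t`` aligns the streams.
    ``correlation_profile`` holds ``(candidate offset s, score)`` rows and
    ``lag_index`` is the argmax row.
    """

    delta_t: float
    lag_index: int
    correlation_profile: np.ndarray


@dataclass
class FrameTransform:
    """Rigid transform from ``from_frame`` to ``to_frame``.

    Points map as ``R p + d``; free vectors map as ``R v``. Rotation is a
    scalar-first unit quaternion; rotation-only transforms carry d = 0.
    """

    rotation: np.ndarray
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    from_frame: str = ""
    to_frame: str = ""

    def __post_init__(self):
        self.rotation = quat.qnormalize(np.asarray(self.rotation, dtype=float))
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    @property
    def matrix(self) -> np.ndarray:
        return quat.as_rotation(self.rotation).as_matrix()

    def apply_points(self, p: np.ndarray) -> np.ndarray:
        return quat.rotate_vector(self.rotation, p) + self.translation

    def apply_vectors(self, v: np.ndarray) -> np.ndarray:
        return quat.rotate_vector(self.rotation, v)

    def apply_orientations(self, q: np.ndarray) -> np.ndarray:
        return quat.qnormalize(quat.qmul(self.rotation, q))

    def inverse(self) -> "FrameTransform":
        rinv = quat.qconj(self.rotation)
        return FrameTransform(
            rinv,
            -quat.rotate_vector(rinv, self.translation),
            from_frame=self.to_frame,
            to_frame=self.from_frame,
        )

    def compose(self, other: "FrameTransform") -> "FrameTransform":
        """self ∘ other: apply ``other`` first, then ``self``."""
        return FrameTransform(
            quat.qmul(self.rotation, other.rotation),
            quat.rotate_vector(self.rotation, other.translation) + self.translation,
            from_frame=other.from_frame,
            to_frame=self.to_frame,
        )


@dataclass
class FrameTree:
    """Collection of frame transforms with path composition."""

    transforms: dict = field(default_factory=dict)
    estimation_window: float = 30.0

    def add(self, transform: FrameTransform) -> None:
        self.transforms[(transform.from_frame, transform.to_frame)] = transform

    def get(self, from_frame: str, to_frame: str) -> FrameTransform:
        """Transform along the (possibly multi-hop) path between two frames."""
        if from_frame == to_frame:
            return FrameTransform(quat.IDENTITY, np.zeros(3), from_frame, to_frame)
        # BFS over direct and inverted edges
        edges = {}
        for (a, b), tr in self.transforms.items():
            edges.setdefault(a, []).append((b, tr))
            edges.setdefault(b, []).append((a, tr.inverse()))
        frontier = [(from_frame, FrameTransform(quat.IDENTITY, np.zeros(3), from_frame, from_frame))]
        seen = {from_frame}
        while frontier:
            node, acc = frontier.pop(0)
            for nxt, tr in edges.get(node, []):
                if nxt in seen:
                    continue
                comp = tr.compose(acc)
                comp.from_frame, comp.to_frame = from_frame, nxt
                if nxt == to_frame:
                    return comp
                seen.add(nxt)
                frontier.append((nxt, comp))
        raise KeyError(f"no path from {from_frame!r} to {to_frame!r} in frame tree")


# ---------------------------------------------------------------------------
# time synchronization
# ---------------------------------------------------------------------------

def _norm_series(stream):
    """(t, ‖·‖) pairs from an angular-velocity-like input."""
    if isinstance(stream, KinematicTrajectory):
        return stream.t, np.linalg.norm(stream.omega, axis=1)
    if isinstance(stream, ImuTrajectory):
        return stream.t, np.linalg.norm(stream.gyro, axis=1)
    t, x = stream
    x = np.asarray(x, dtype=float)
    if x.ndim == 2:
        x = np.linalg.norm(x, axis=1)
    return np.asarray(t, dtype=float), x


def estimate_time_offset(omega_hat, omega, max_lag: float = 10.0,
                         demean: bool = False) -> SyncResult:
    """Clock offset from cross-correlating angular-velocity norms.

    Both norm series are resampled to a common uniform grid at the coarser
    of the two native rates, and the raw (un-demeaned by default) sliding
    dot product ``Σ ‖ω̂_i‖·‖ω_{i+k}‖`` is maximized over lags within
    ``±max_lag`` seconds. The returned ``delta_t`` is positive when the
    device clock runs ahead (its timestamps are larger than the gold
    standard's for the same event).
    """
    if max_lag <= 0:
        raise ValidationError("max_lag must be positive")
    t_hat, a_hat = _norm_series(omega_hat)
    t_ref, a_ref = _norm_series(omega)
    if np.ptp(a_hat) == 0 or np.ptp(a_ref) == 0:
        raise DegenerateSignalError("flat angular-velocity norm; cannot synchronize")
    dt = max(np.median(np.diff(t_hat)), np.median(np.diff(t_ref)))
    grid_hat = np.arange(t_hat[0], t_hat[-1] + dt / 2, dt)
    grid_ref = np.arange(t_ref[0], t_ref[-1] + dt / 2, dt)
    x_hat = np.interp(grid_hat, t_hat, a_hat)
    x_ref = np.interp(grid_ref, t_ref, a_ref)
    if demean:
        x_hat = x_hat - x_hat.mean()
        x_ref = x_ref - x_ref.mean()

    # S(k) = sum_i x_hat[i] * x_ref[i + k]
    full = np.correlate(x_hat, x_ref, mode="full")
    n_ref = len(x_ref)
    ks = (n_ref - 1) - np.arange(len(full))
    start_gap = grid_hat[0] - grid_ref[0]
    deltas = start_gap - ks * dt
    overlap = np.minimum(len(x_hat), n_ref + ks) - np.maximum(0, ks)
    keep = (np.abs(deltas) <= max_lag) & (overlap * dt >= 2.0)
    if not np.any(keep):
        raise InsufficientOverlapError(
            "no candidate lag with at least 2 s of overlap within max_lag"
        )
    profile = np.column_stack([deltas[keep], full[keep]])
    order = np.argsort(profile[:, 0])
    profile = profile[order]
    lag_index = int(np.argmax(profile[:, 1]))
    return SyncResult(float(profile[lag_index, 0]), lag_index, profile)


def tap_offset_from_accel(accel_a: ImuTrajectory, accel_b: ImuTrajectory,
                          search_window: float = 10.0,
                          highpass_hz: float = 10.0) -> float:
    """Clock offset from the transient of tapping two IMUs together.

    Detects, in each stream, the global maximum of the high-pass-filtered
    accelerometer norm within ``search_window`` seconds of stream start
    and returns the difference of the two peak times (a − b). A peak must
    exceed 3× the window's median absolute deviation.
    """
    from scipy.signal import butter, filtfilt

    def peak_time(imu: ImuTrajectory) -> float:
        t = imu.t
        norm = np.linalg.norm(imu.accel, axis=1)
        fs = 1.0 / np.median(np.diff(t))
        wn = min(highpass_hz, 0.45 * fs) / (fs / 2.0)
        b, a = butter(4, wn, btype="highpass")
        filt = np.abs(filtfilt(b, a, norm))
        window = t <= t[0] + search_window
        seg = filt[window]
        mad = np.median(np.abs(seg - np.median(seg)))
        i = int(np.argmax(seg))
        # a tap must stand out 3x above the window's MAD (and above the
        # numerical residue a transient-free stream leaves after filtering)
        if seg[i] < max(3.0 * mad, 1e-6):
            raise DegenerateSignalError("no tap transient found in search window")
        return float(t[window][i])

    return peak_time(accel_a) - peak_time(accel_b)


# ---------------------------------------------------------------------------
# resampling
# ---------------------------------------------------------------------------

def resample_to(traj, target_t: np.ndarray):
    """Interpolate a trajectory onto new timestamps (no extrapolation).

    Positions and velocities are linearly interpolated; orientations use
    squad interpolation and remain unit quaternions.
    """
    target_t = np.asarray(target_t, dtype=float)
    if target_t.min() < traj.t[0] - 1e-9 or target_t.max() > traj.t[-1] + 1e-9:
        raise ValidationError("target timestamps outside the source time span")

    def lin(y):
        return np.column_stack([np.interp(target_t, traj.t, y[:, j]) for j in range(y.shape[1])])

    if isinstance(traj, PoseTrajectory):
        return PoseTrajectory(
            target_t, lin(traj.p), quat.squad_interpolate(traj.t, traj.q, target_t),
            traj.frame_id,
        )
    if isinstance(traj, KinematicTrajectory):
        return KinematicTrajectory(target_t, lin(traj.v), lin(traj.omega), traj.frame_id)
    raise TypeError(f"cannot resample {type(traj).__name__}")


# ---------------------------------------------------------------------------
# frame estimation
# ---------------------------------------------------------------------------

def _kabsch(source: np.ndarray, target: np.ndarray, weights=None):
    """Rotation R (and centroids) minimizing Σ w‖R s + d − t‖², det(R) = +1."""
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    if weights is None:
        weights = np.ones(len(source))
    w = weights / weights.sum()
    cs = w @ source
    ct = w @ target
    h = (target - ct).T @ ((source - cs) * w[:, None])
    u, s, vt = np.linalg.svd(h)
    if len(source) >= 3 and s[0] > 0 and s[1] < 1e-9 * s[0]:
        raise DegenerateGeometryError("point set is (near-)collinear; registration ill-posed")
    d = np.sign(np.linalg.det(u @ vt))
    r = u @ np.diag([1.0, 1.0, d]) @ vt
    return r, cs, ct


def register_world_frame(p_hat: np.ndarray, p: np.ndarray,
                         from_frame: str = "W_hat", to_frame: str = "W") -> FrameTransform:
    """Rigid (no scale) registration of device positions to gold standard.

    Solves ``min Σ‖R p̂ + d − p‖²`` in closed form via the SVD of the
    cross-covariance with determinant correction.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    p = np.asarray(p, dtype=float)
    if p_hat.shape != p.shape or len(p_hat) < 3:
        raise ValidationError("need equal-length position series with >= 3 samples")
    r, cs, ct = _kabsch(p_hat, p)
    d = ct - r @ cs
    from scipy.spatial.transform import Rotation
    return FrameTransform(quat.from_rotation(Rotation.from_matrix(r)), d,
                          from_frame, to_frame)


def solve_attitude(source: np.ndarray, target: np.ndarray) -> np.ndarray:
    """Rotation matrix minimizing Σ‖R s_i − t_i‖² (Wahba's problem).

    Equal weights per observation; determinant-corrected SVD solution.
    """
    source = np.asarray(source, dtype=float)
    target = np.asarray(target, dtype=float)
    b = target.T @ source
    u, s, vt = np.linalg.svd(b)
    if s[0] > 0 and s[1] < 1e-12 * s[0]:
        raise DegenerateGeometryError("observation directions are degenerate")
    d = np.sign(np.linalg.det(u @ vt))
    return u @ np.diag([1.0, 1.0, d]) @ vt


FORWARD = np.array([1.0, 0.0, 0.0])
UP = np.array([0.0, 0.0, 1.0])


def _unit_rows(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v, axis=-1, keepdims=True)
    return v / n


def estimate_calibrated_frame(v_body: np.ndarray, g_body: np.ndarray,
                              from_frame: str = "B_hat", to_frame: str = "C_hat",
                              mode: str = "instantaneous") -> FrameTransform:
    """Rotation taking a body frame to its calibrated frame.

    The calibrated frame centers the heading direction (instantaneous
    linear velocity) along +x and the gravity direction along −z. Solved
    as a least-squares attitude problem over the observation pairs
    ``{v_i/‖v_i‖ → +x, g_i/‖g_i‖ → −z}`` (``mode="instantaneous"``) or
    over the two normalized mean directions (``mode="mean"``).
    """
    v_unit = _unit_rows(v_body)
    g_unit = _unit_rows(g_body)
    v_mean = _unit_rows(v_unit.mean(axis=0))
    g_mean = _unit_rows(g_unit.mean(axis=0))
    angle = np.degrees(np.arccos(np.clip(abs(v_mean @ g_mean), -1.0, 1.0)))
    if angle < 10.0:  # mean heading within 10° of (anti)parallel to gravity
        raise DegenerateGeometryError(
            "mean heading nearly parallel to gravity; calibrated frame ill-conditioned"
        )
    if mode == "mean":
        source = np.vstack([v_mean, g_mean])
        target = np.vstack([FORWARD, -UP])
    elif mode == "instantaneous":
        source = np.vstack([v_unit, g_unit])
        target = np.vstack(
            [np.tile(FORWARD, (len(v_unit), 1)), np.tile(-UP, (len(g_unit), 1))]
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")
    r = solve_attitude(source, target)
    from scipy.spatial.transform import Rotation
    return FrameTransform(quat.from_rotation(Rotation.from_matrix(r)),
                          np.zeros(3), from_frame, to_frame)


def calibrate_gold_to_device(v_gold: np.ndarray, g_gold: np.ndarray,
                             v_dev_cal: np.ndarray, g_dev_cal: np.ndarray,
                             from_frame: str = "B", to_frame: str = "C") -> FrameTransform:
    """Rotation aligning gold-standard body vectors to the device's calibrated ones.

    Pairs the per-sample gold heading and gravity directions with their
    device counterparts (already expressed in the device calibrated
    frame) and solves the same rotation-only attitude problem.
    """
    source = np.vstack([_unit_rows(v_gold), _unit_rows(g_gold)])
    target = np.vstack([_unit_rows(v_dev_cal), _unit_rows(g_dev_cal)])
    if source.shape != target.shape:
        raise ValidationError("gold and device series must pair one-to-one")
    r = solve_attitude(source, target)
    from scipy.spatial.transform import Rotation
    return FrameTransform(quat.from_rotation(Rotation.from_matrix(r)),
                          np.zeros(3), from_frame, to_frame)


WORLD_FRAMES = {"W", "W_hat"}


def apply_frame_tree(traj, tree: FrameTree, target_frame: str):
    """Express a trajectory in another frame of the tree.

    For pose trajectories between world frames, positions and
    orientations are composed through the chain. For kinematic
    trajectories, velocity vectors are rotated only (no translation).
    """
    tr = tree.get(traj.frame_id, target_frame)
    if isinstance(traj, PoseTrajectory):
        return PoseTrajectory(
            traj.t, tr.apply_points(traj.p), tr.apply_orientations(traj.q), target_frame
        )
    if isinstance(traj, KinematicTrajectory):
        return KinematicTrajectory(
            traj.t, tr.apply_vectors(traj.v), tr.apply_vectors(traj.omega), target_frame
        )
    raise TypeError(f"cannot transform {type(traj).__name__}")
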