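"""Kinematic derivation from pose streams.

Linear velocity is the time derivative of position, v = ṗ; angular
velocity is recovered from the quaternion stream as the imaginary part
of ``2 q* q̇`` and is expressed in the body frame. Derivatives use
second-order central differences on the (possibly non-uniform) sample
grid with second-order one-sided stencils at the ends.

Scalar speed is the norm of the earth-horizontal velocity components,
``v = sqrt(vx² + vy²)``, valid when velocity is expressed in a z-up
world frame.

Orientation relative to gravity is summarized by roll and pitch angles
of the gravity direction g in the calibrated body frame (x forward,
y left, z up):

* roll  α = arctan(gy / gz)   (two-argument form; positive = rightward roll)
* pitch β = −arcsin(gx / ‖g‖) (positive = forward pitch)

Yaw error between two orientations is the geodesic distance between
their yaw components ``q_γ = [sqrt(1 − qz²), 0, 0, qz]``:
``Δγ = arccos(2⟨q̂_γ, q_γ⟩² − 1)``.

Direction angles (heading of v, or instantaneous rotation axis of ω) in
the calibrated body frame are azimuth ``θ = −arctan(y/x)`` (two-argument
form, positive rightward) and elevation ``φ = arcsin(z/‖·‖)`` (positive
upward).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import quat
from .io_model import KinematicTrajectory, PoseTrajectory, ValidationError

DOWN = np.array([0.0, 0.0, -1.0])  # gravity direction in any z-up world frame

__all__ = [
    "SpeedSeries",
    "GravitySeries",
    "DirectionAngles",
    "differentiate_position",
    "angular_velocity_from_orientation",
    "derive_kinematics",
    "horizontal_speed",
    "gravity_in_calibrated_frame",
    "yaw_component",
    "yaw_difference",
    "direction_angles",
    "rotate_vector",
]


@dataclass
class SpeedSeries:
    """Scalar (earth-horizontal) speed in m/s."""

    t: np.ndarray
    v: np.ndarray

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)

    def __len__(self):
        return len(self.t)


@dataclass
class GravitySeries:
    """Gravity direction in a calibrated body frame plus roll/pitch angles (°)."""

    t: np.ndarray
    g: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __len__(self):
        return len(self.t)


@dataclass
class DirectionAngles:
    """Azimuth/elevation (°) of a vector series, with zero-norm samples flagged."""

    t: np.ndarray
    theta: np.ndarray
    phi: np.ndarray
    valid: np.ndarray

    @property
    def n_excluded(self) -> int:
        return int((~self.valid).sum())


def _gradient(y: np.ndarray, t: np.ndarray) -> np.ndarray:
    if len(t) < 3:
        raise ValidationError("need at least 3 samples to differentiate")
    return np.gradient(y, t, axis=0, edge_order=2)


def differentiate_position(traj: PoseTrajectory) -> KinematicTrajectory:
    """Linear velocity v = ṗ in the trajectory's world frame (ω left zero)."""
    v = _gradient(traj.p, traj.t)
    return KinematicTrajectory(traj.t, v, np.zeros_like(v), traj.frame_id)


def angular_velocity_from_orientation(traj: PoseTrajectory) -> np.ndarray:
    """Body-frame angular velocity ω = Im(2 q* q̇) in rad/s, shape (n, 3).

    The quaternion stream is hemisphere-aligned before differentiation so
    the double cover does not corrupt q̇.
    """
    q = quat.hemisphere_align(traj.q)
    qdot = _gradient(q, traj.t)
    return 2.0 * quat.qmul(quat.qconj(q), qdot)[:, 1:]


def derive_kinematics(traj: PoseTrajectory) -> KinematicTrajectory:
    """v = ṗ (world frame) and body-frame ω from one pose stream."""
    v = _gradient(traj.p, traj.t)
    omega = angular_velocity_from_orientation(traj)
    return KinematicTrajectory(traj.t, v, omega, traj.frame_id)


def horizontal_speed(kin_or_v, t=None) -> SpeedSeries:
    """Earth-horizontal speed ‖(vx, vy)‖ of a z-up world-frame velocity."""
    if isinstance(kin_or_v, KinematicTrajectory):
        v, t = kin_or_v.v, kin_or_v.t
    else:
        v = np.asarray(kin_or_v, dtype=float)
        if t is None:
            t = np.arange(len(v), dtype=float)
    return SpeedSeries(t, np.hypot(v[:, 0], v[:, 1]))


def gravity_body(traj: PoseTrajectory) -> np.ndarray:
    """World down-direction expressed in the trajectory's body frame, (n, 3)."""
    return quat.rotate_vector(quat.qconj(traj.q), DOWN)


def roll_pitch_from_gravity(g: np.ndarray):
    """Roll α and pitch β in degrees from gravity direction(s) g.

    α uses the two-argument arctangent ``atan2(−gy, −gz)``, which reduces
    to ``arctan(gy/gz)`` in the ordinary near-upright case (gz < 0) while
    staying well-defined through ±90° of roll.
    """
    g = np.asarray(g, dtype=float)
    norm = np.linalg.norm(g, axis=-1)
    alpha = np.degrees(np.arctan2(-g[..., 1], -g[..., 2]))
    beta = -np.degrees(np.arcsin(np.clip(g[..., 0] / norm, -1.0, 1.0)))
    return alpha, beta


def gravity_in_calibrated_frame(traj: PoseTrajectory, calibration=None) -> GravitySeries:
    """Gravity direction per sample in the (calibrated) body frame.

    ``calibration``, if given, is a rotation matrix or unit quaternion
    re-expressing body-frame vectors in the calibrated frame.
    """
    g = gravity_body(traj)
    if calibration is not None:
        calibration = np.asarray(calibration, dtype=float)
        if calibration.shape == (4,):
            g = quat.rotate_vector(calibration, g)
        else:
            g = g @ calibration.T
    alpha, beta = roll_pitch_from_gravity(g)
    return GravitySeries(traj.t, g, alpha, beta)


def yaw_component(q: np.ndarray) -> np.ndarray:
    """Yaw-component quaternion ``[sqrt(1 − qz²), 0, 0, qz]``.

    ``qz`` magnitudes marginally above 1 (floating point) are clamped.
    Input quaternions should be in the qw ≥ 0 hemisphere; the sign is
    fixed up internally so q and −q give the same yaw component.
    """
    q = np.asarray(q, dtype=float)
    q = np.where(q[..., :1] < 0.0, -q, q)
    qz = np.clip(q[..., 3], -1.0, 1.0)
    w = np.sqrt(np.clip(1.0 - qz * qz, 0.0, 1.0))
    out = np.zeros(q.shape)
    out[..., 0] = w
    out[..., 3] = qz
    return out


def yaw_difference(q_hat: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Geodesic distance Δγ (degrees, in [0, 180]) between yaw components.

    ``arccos(2⟨q̂_γ, q_γ⟩² − 1)`` equals ``2 arccos |⟨q̂_γ, q_γ⟩|`` by the
    double-angle identity; the latter is evaluated in half-angle atan2
    form, which keeps full precision for near-identical orientations.
    """
    a = yaw_component(q_hat)
    b = yaw_component(q)
    b = np.where(np.sum(a * b, axis=-1, keepdims=True) < 0.0, -b, b)
    half = np.arctan2(
        np.linalg.norm(a - b, axis=-1), np.linalg.norm(a + b, axis=-1)
    )
    return np.degrees(4.0 * half)


def direction_angles(vectors: np.ndarray, t=None) -> DirectionAngles:
    """Azimuth θ and elevation φ (degrees) of body-frame vectors.

    θ = atan2(−y, x) in (−180, 180] (positive rightward), φ = arcsin(z/‖·‖)
    (positive upward). Zero-norm samples are flagged invalid and carry NaN.
    """
    v = np.asarray(vectors, dtype=float)
    if t is None:
        t = np.arange(len(v), dtype=float)
    norm = np.linalg.norm(v, axis=-1)
    valid = norm > 0.0
    theta = np.full(len(v), np.nan)
    phi = np.full(len(v), np.nan)
    theta[valid] = np.degrees(np.arctan2(-v[valid, 1], v[valid, 0]))
    phi[valid] = np.degrees(np.arcsin(np.clip(v[valid, 2] / norm[valid], -1.0, 1.0)))
    return DirectionAngles(np.asarray(t, dtype=float), theta, phi, valid)


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """rot(q, v) = q v q⁻¹ (norm-preserving)."""
    return quat.rotate_vector(q, v)
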