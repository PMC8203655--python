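"""Unit-quaternion algebra and spherical quadrangle (squad) interpolation.

Conventions used throughout the package:

* quaternions are scalar-first ``(w, x, y, z)`` in Hamilton convention,
  stored as float arrays of shape ``(..., 4)``;
* all frames are right-handed; a pose quaternion maps body-frame
  coordinates to world-frame coordinates;
* the double cover is resolved by hemisphere alignment
  (:func:`hemisphere_align`) before any differentiation or interpolation.

scipy's :class:`~scipy.spatial.transform.Rotation` is used for
matrix conversions; the interpolation and group operations needed by the
evaluation pipeline are implemented here so they vectorize over whole
trajectories.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "qmul",
    "qconj",
    "qinv",
    "qnormalize",
    "hemisphere_align",
    "rotate_vector",
    "qexp",
    "qlog",
    "slerp",
    "squad",
    "squad_interpolate",
    "from_axis_angle",
    "quat_angle_deg",
    "as_rotation",
    "from_rotation",
]

IDENTITY = np.array([1.0, 0.0, 0.0, 0.0])


def qmul(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Hamilton product ``a ⊗ b``, broadcasting over leading axes."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    aw, ax, ay, az = np.moveaxis(a, -1, 0)
    bw, bx, by, bz = np.moveaxis(b, -1, 0)
    return np.stack(
        [
            aw * bw - ax * bx - ay * by - az * bz,
            aw * bx + ax * bw + ay * bz - az * by,
            aw * by - ax * bz + ay * bw + az * bx,
            aw * bz + ax * by - ay * bx + az * bw,
        ],
        axis=-1,
    )


def qconj(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q * np.array([1.0, -1.0, -1.0, -1.0])


def qinv(q: np.ndarray) -> np.ndarray:
    """Inverse; equals the conjugate for unit quaternions."""
    q = np.asarray(q, dtype=float)
    return qconj(q) / np.sum(q * q, axis=-1, keepdims=True)


def qnormalize(q: np.ndarray) -> np.ndarray:
    q = np.asarray(q, dtype=float)
    return q / np.linalg.norm(q, axis=-1, keepdims=True)


def hemisphere_align(q: np.ndarray) -> np.ndarray:
    """Flip signs along axis 0 so consecutive quaternions have positive dot.

    Resolves the double-cover ambiguity of a quaternion time series; the
    represented rotations are unchanged.
    """
    q = np.array(q, dtype=float)
    if q.ndim != 2 or q.shape[0] == 0:
        return q
    dots = np.sum(q[:-1] * q[1:], axis=-1)
    flips = np.cumprod(np.where(dots < 0.0, -1.0, 1.0))
    q[1:] *= flips[:, None]
    return q


def rotate_vector(q: np.ndarray, v: np.ndarray) -> np.ndarray:
    """rot(q, v) = q v q⁻¹ — rotate vector(s) by unit quaternion(s).

    Broadcasts: ``q`` of shape ``(..., 4)`` with ``v`` of shape ``(..., 3)``.
    """
    q = np.asarray(q, dtype=float)
    v = np.asarray(v, dtype=float)
    w = q[..., :1]
    u = q[..., 1:]
    # Rodrigues-style expansion of q v q*
    uv = np.cross(u, v)
    return v + 2.0 * (w * uv + np.cross(u, uv))


def qexp(v: np.ndarray) -> np.ndarray:
    """Exponential of a pure quaternion given as a 3-vector."""
    v = np.asarray(v, dtype=float)
    theta = np.linalg.norm(v, axis=-1, keepdims=True)
    w = np.cos(theta)
    small = theta < 1e-12
    sinc = np.where(small, 1.0, np.sin(np.where(small, 1.0, theta)) / np.where(small, 1.0, theta))
    return np.concatenate([w, sinc * v], axis=-1)


def qlog(q: np.ndarray) -> np.ndarray:
    """Logarithm of a unit quaternion, returned as a 3-vector."""
    q = np.asarray(q, dtype=float)
    w = np.clip(q[..., :1], -1.0, 1.0)
    u = q[..., 1:]
    un = np.linalg.norm(u, axis=-1, keepdims=True)
    theta = np.arctan2(un, w)
    small = un < 1e-12
    scale = np.where(small, 1.0, theta / np.where(small, 1.0, un))
    return scale * u


def slerp(q0: np.ndarray, q1: np.ndarray, u) -> np.ndarray:
    """Geodesic interpolation between unit quaternions at fraction ``u``."""
    q0 = np.asarray(q0, dtype=float)
    q1 = np.asarray(q1, dtype=float)
    u = np.asarray(u, dtype=float)[..., None]
    rel = qmul(qinv(q0), q1)
    return qnormalize(qmul(q0, qexp(u * qlog(rel))))


def _inner_points(q: np.ndarray) -> np.ndarray:
    """Squad control points s_i from neighboring samples.

    ``s_i = q_i exp(-(log(q_i⁻¹ q_{i+1}) + log(q_i⁻¹ q_{i-1})) / 4)``;
    endpoints use the sample itself.
    """
    n = q.shape[0]
    s = q.copy()
    if n < 3:
        return s
    qi = q[1:-1]
    qinv_i = qinv(qi)
    arg = -0.25 * (qlog(qmul(qinv_i, q[2:])) + qlog(qmul(qinv_i, q[:-2])))
    s[1:-1] = qnormalize(qmul(qi, qexp(arg)))
    return s


def squad(q0, q1, s0, s1, u) -> np.ndarray:
    """Spherical quadrangle interpolation between q0 and q1 at fraction u."""
    u = np.asarray(u, dtype=float)
    outer = slerp(q0, q1, u)
    inner = slerp(s0, s1, u)
    return slerp(outer, inner, 2.0 * u * (1.0 - u))


def squad_interpolate(t: np.ndarray, q: np.ndarray, t_query: np.ndarray) -> np.ndarray:
    """C¹-continuous quaternion interpolation of a time series.

    Parameters
    ----------
    t
        Strictly increasing sample times, shape (n,).
    q
        Unit quaternions at those times, shape (n, 4).
    t_query
        Query times within ``[t[0], t[-1]]``.

    Returns
    -------
    Unit quaternions at the query times, shape (m, 4).
    """
    t = np.asarray(t, dtype=float)
    q = hemisphere_align(qnormalize(np.asarray(q, dtype=float)))
    t_query = np.asarray(t_query, dtype=float)
    if t.shape[0] < 2:
        raise ValueError("need at least two samples to interpolate")
    if t_query.min() < t[0] - 1e-9 or t_query.max() > t[-1] + 1e-9:
        raise ValueError("query times outside the source time span")
    s = _inner_points(q)
    idx = np.clip(np.searchsorted(t, t_query, side="right") - 1, 0, t.shape[0] - 2)
    u = (t_query - t[idx]) / (t[idx + 1] - t[idx])
    u = np.clip(u, 0.0, 1.0)
    return qnormalize(squad(q[idx], q[idx + 1], s[idx], s[idx + 1], u))


def from_axis_angle(axis, angle_rad: float) -> np.ndarray:
    """Unit quaternion for a rotation of ``angle_rad`` about ``axis``."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    return np.concatenate([[np.cos(angle_rad / 2.0)], np.sin(angle_rad / 2.0) * axis])


def quat_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Geodesic angle in degrees between the rotations a and b represent.

    Half-angle atan2 form; keeps full precision for near-identical
    rotations where the arccos of the dot product bottoms out near 1e-6.
    """
    a = qnormalize(a)
    b = qnormalize(b)
    b = np.where(np.sum(a * b, axis=-1, keepdims=True) < 0.0, -b, b)
    half = np.arctan2(np.linalg.norm(a - b, axis=-1), np.linalg.norm(a + b, axis=-1))
    return np.degrees(4.0 * half)


def as_rotation(q: np.ndarray) -> Rotation:
    return Rotation.from_quat(np.asarray(q, dtype=float), scalar_first=True)


def from_rotation(r: Rotation) -> np.ndarray:
    return np.asarray(r.as_quat(scalar_first=True), dtype=float)
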