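"""Performance metrics comparing a device pose/kinematic stream to a gold standard.

All functions operate on temporally aligned, equal-length, frame-registered
series. Positions are expected in the shared world frame W; velocity and
angular-velocity vectors in the respective calibrated body frames. Units
follow the reporting conventions of the field: metres, degrees, percent,
degrees per hour, and °/s for angular-velocity magnitudes.

The suite:

========  =====  =======================================================
name      units  meaning
========  =====  =======================================================
TLE       %      relative trajectory-length difference (L̂ − L)/L
ATE       m      RMS of per-sample position distances
RTE       m      RMS of windowed relative displacement error, with the
                 yaw error at the window start removed
TDr       %      final position discrepancy relative to length L
GDE       °      mean angle between gravity-direction estimates
GDE_alpha °      mean signed roll difference
GDE_beta  °      mean signed pitch difference
AYE       °      RMS of the yaw-angle difference Δγ
RYE       °      RMS of windowed Δγ increments
YDr       °/h    final Δγ per unit trajectory duration
SpE       %      mean relative horizontal-speed difference
HDE       °      mean angle between linear-velocity vectors
HDE_theta °      mean signed heading-azimuth difference
HDE_phi   °      mean signed heading-elevation difference
LVME      m/s    mean linear-velocity magnitude difference
AVDE      °      mean angle between angular-velocity vectors
AVDE_theta °     mean signed rotation-axis azimuth difference
AVDE_phi  °      mean signed rotation-axis elevation difference
AVME      °/s    mean angular-velocity magnitude difference
========  =====  =======================================================

Sample exclusions (re-localization artifacts above 5 m/s for trajectory
length, gold speed below 0.1 m/s for the velocity metrics, Δγ outside
its 1st–99th percentile for the yaw metrics) are applied exactly as
documented on each function, and every function reports how many samples
it used and excluded.
"""

from __future__ import annotations

import numpy as np

from . import quat
from .io_model import ValidationError
from .kinematics import direction_angles, yaw_component

__all__ = [
    "trajectory_length",
    "tle",
    "translation_metrics",
    "yaw_metrics",
    "gravity_metrics",
    "speed_error",
    "linear_velocity_metrics",
    "angular_velocity_metrics",
]


def _wrap_deg(x: np.ndarray) -> np.ndarray:
    """Wrap angle differences to (−180, 180]."""
    return -(-(np.asarray(x) + 180.0) % 360.0 - 180.0)


def _vector_angle_deg(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    # atan2 form of arccos(<a,b>/|a||b|): identical value, but keeps full
    # precision for nearly parallel vectors where arccos degrades
    cross = np.linalg.norm(np.cross(a, b), axis=-1)
    dot = np.sum(a * b, axis=-1)
    return np.degrees(np.arctan2(cross, dot))


def trajectory_length(p: np.ndarray, t: np.ndarray | None = None,
                      artifact_speed: float = 5.0):
    """Earth-horizontal path length, excluding re-localization artifacts.

    ``L = Σ ‖p_xy,i − p_xy,i−1‖`` over consecutive pairs; a pair whose
    implied instantaneous speed (3-D displacement / Δt) exceeds
    ``artifact_speed`` contributes nothing and is counted as excluded.

    Returns ``(L, n_excluded_pairs)``.
    """
    p = np.asarray(p, dtype=float)
    if len(p) < 2:
        raise ValidationError("need at least 2 samples for a trajectory length")
    if t is None:
        t = np.arange(len(p), dtype=float)
    t = np.asarray(t, dtype=float)
    seg_xy = np.linalg.norm(np.diff(p[:, :2], axis=0), axis=1)
    speed = np.linalg.norm(np.diff(p, axis=0), axis=1) / np.diff(t)
    keep = speed <= artifact_speed
    return float(seg_xy[keep].sum()), int((~keep).sum())


def tle(L_hat: float, L: float) -> float:
    """Trajectory length error, percent: 100 (L̂ − L)/L."""
    if L <= 0:
        raise ValidationError("gold-standard trajectory length must be positive")
    return 100.0 * (L_hat - L) / L


def translation_metrics(p_hat: np.ndarray, p: np.ndarray,
                        q_hat: np.ndarray, q: np.ndarray,
                        k: int = 50, t: np.ndarray | None = None,
                        L: float | None = None,
                        artifact_speed: float = 5.0) -> dict:
    """Absolute/relative translation error and translation drift.

    * ``ATE = sqrt(mean ‖p̂_i − p_i‖²)``
    * ``RTE = sqrt(mean_i ‖(p̂_{i+k} − p̂_i) − rot(q̂_γ,i q_γ,i⁻¹, p_{i+k} − p_i)‖²)``
      averaged over the n − k valid windows; the rot(·) term removes the
      yaw error accumulated up to the window start.
    * ``TDr = 100 ‖p̂_n − p_n‖ / L`` (percent of gold trajectory length).
    * ``TDr_rate = ‖p̂_n − p_n‖ / T`` in m/h is also reported when
      timestamps are available.
    """
    p_hat = np.asarray(p_hat, dtype=float)
    p = np.asarray(p, dtype=float)
    n = len(p)
    if len(p_hat) != n or len(q_hat) != n or len(q) != n:
        raise ValidationError("aligned series must have equal lengths")
    if not 1 <= k < n:
        raise ValidationError(f"window k={k} must satisfy 1 <= k < n={n}")
    ate = float(np.sqrt(np.mean(np.sum((p_hat - p) ** 2, axis=1))))

    rel_hat = p_hat[k:] - p_hat[:-k]
    rel = p[k:] - p[:-k]
    q_corr = quat.qmul(yaw_component(q_hat[:-k]), quat.qconj(yaw_component(q[:-k])))
    resid = rel_hat - quat.rotate_vector(q_corr, rel)
    rte = float(np.sqrt(np.mean(np.sum(resid ** 2, axis=1))))

    if L is None:
        L, _ = trajectory_length(p, t, artifact_speed)
    final = float(np.linalg.norm(p_hat[-1] - p[-1]))
    out = {"ATE": ate, "RTE": rte, "TDr": 100.0 * final / L, "n": n, "k": k}
    if t is not None:
        hours = (np.asarray(t)[-1] - np.asarray(t)[0]) / 3600.0
        out["TDr_rate"] = final / hours
    return out


def yaw_metrics(delta_gamma: np.ndarray, t: np.ndarray, k: int = 50,
                percentile_bounds=(1.0, 99.0)) -> dict:
    """Absolute/relative yaw error and yaw drift from the Δγ series.

    Samples with Δγ outside its [1st, 99th] percentile are excluded
    first (per trajectory); AYE is the RMS of the retained Δγ, RYE the
    RMS of retained ``Δγ_{i+k} − Δγ_i`` increments, and YDr the last
    retained Δγ divided by the trajectory duration in hours.
    """
    dg = np.asarray(delta_gamma, dtype=float)
    t = np.asarray(t, dtype=float)
    n = len(dg)
    if n <= k:
        raise ValidationError(f"need more than k={k} samples")
    lo, hi = np.percentile(dg, percentile_bounds)
    keep = (dg >= lo) & (dg <= hi)
    if keep.sum() < 2:
        raise ValidationError("fewer than 2 samples retained after percentile exclusion")
    aye = float(np.sqrt(np.mean(dg[keep] ** 2)))
    pair = keep[k:] & keep[:-k]
    rye = float(np.sqrt(np.mean((dg[k:][pair] - dg[:-k][pair]) ** 2))) if pair.any() else 0.0
    hours = (t[-1] - t[0]) / 3600.0
    last = np.nonzero(keep)[0][-1]
    ydr = float(dg[last] / hours)
    return {
        "AYE": aye, "RYE": rye, "YDr": ydr,
        "n_used": int(keep.sum()), "n_excluded": int(n - keep.sum()),
    }


def gravity_metrics(g_hat: np.ndarray, g: np.ndarray,
                    alpha_hat=None, alpha=None, beta_hat=None, beta=None) -> dict:
    """Gravity direction error and its signed roll/pitch components.

    ``GDE`` is the mean per-sample angle between the two gravity-direction
    estimates; ``GDE_alpha``/``GDE_beta`` are mean signed roll/pitch
    differences (computed from the vectors when angles are not supplied).
    """
    from .kinematics import roll_pitch_from_gravity

    g_hat = np.asarray(g_hat, dtype=float)
    g = np.asarray(g, dtype=float)
    if g_hat.shape != g.shape:
        raise ValidationError("gravity series must have equal shapes")
    if np.any(np.linalg.norm(g_hat, axis=-1) == 0) or np.any(np.linalg.norm(g, axis=-1) == 0):
        raise ValidationError("gravity vectors must be nonzero")
    gde = float(np.mean(_vector_angle_deg(g_hat, g)))
    if alpha_hat is None:
        alpha_hat, beta_hat = roll_pitch_from_gravity(g_hat)
    if alpha is None:
        alpha, beta = roll_pitch_from_gravity(g)
    return {
        "GDE": gde,
        "GDE_alpha": float(np.mean(_wrap_deg(np.asarray(alpha_hat) - np.asarray(alpha)))),
        "GDE_beta": float(np.mean(np.asarray(beta_hat) - np.asarray(beta))),
        "n_used": len(g),
    }


def speed_error(v_hat: np.ndarray, v: np.ndarray,
                min_gold_speed: float = 0.1) -> dict:
    """Mean relative horizontal-speed difference, percent.

    Samples where the gold-standard speed is below ``min_gold_speed``
    are excluded (the relative error diverges as v → 0).
    """
    v_hat = np.asarray(v_hat, dtype=float)
    v = np.asarray(v, dtype=float)
    if v_hat.shape != v.shape:
        raise ValidationError("speed series must have equal lengths")
    keep = v >= min_gold_speed
    if not keep.any():
        raise ValidationError("no samples at or above the gold-speed threshold")
    spe = 100.0 * float(np.mean((v_hat[keep] - v[keep]) / v[keep]))
    return {"SpE": spe, "n_used": int(keep.sum()), "n_excluded": int((~keep).sum())}


def _direction_metrics(v_hat, v, keep, prefix: str):
    both = keep & (np.linalg.norm(v_hat, axis=1) > 0) & (np.linalg.norm(v, axis=1) > 0)
    ang = float(np.mean(_vector_angle_deg(v_hat[both], v[both])))
    da_hat = direction_angles(v_hat[both])
    da = direction_angles(v[both])
    return {
        prefix: ang,
        f"{prefix}_theta": float(np.mean(_wrap_deg(da_hat.theta - da.theta))),
        f"{prefix}_phi": float(np.mean(da_hat.phi - da.phi)),
    }, both


def linear_velocity_metrics(v_hat: np.ndarray, v: np.ndarray,
                            gold_speed: np.ndarray | None = None,
                            min_gold_speed: float = 0.1) -> dict:
    """Heading direction error, its azimuth/elevation parts, and LVME.

    ``gold_speed`` is the gold-standard earth-horizontal speed used for
    the exclusion rule; when omitted, the horizontal norm of ``v`` is
    used (valid when ``v`` is expressed in a z-up frame).
    """
    v_hat = np.asarray(v_hat, dtype=float)
    v = np.asarray(v, dtype=float)
    if v_hat.shape != v.shape:
        raise ValidationError("velocity series must have equal shapes")
    if gold_speed is None:
        gold_speed = np.hypot(v[:, 0], v[:, 1])
    keep = np.asarray(gold_speed) >= min_gold_speed
    if not keep.any():
        raise ValidationError("no samples at or above the gold-speed threshold")
    out, both = _direction_metrics(v_hat, v, keep, "HDE")
    out["LVME"] = float(np.mean(
        np.linalg.norm(v_hat[keep], axis=1) - np.linalg.norm(v[keep], axis=1)
    ))
    out["n_used"] = int(both.sum())
    out["n_excluded"] = int(len(v) - both.sum())
    return out


def angular_velocity_metrics(omega_hat: np.ndarray, omega: np.ndarray,
                             gold_speed: np.ndarray,
                             min_gold_speed: float = 0.1) -> dict:
    """Rotation-axis direction error, its components, and AVME (°/s).

    Exclusion is keyed on the gold-standard *motion* speed (the shared
    low-speed rule), with zero-norm ω samples additionally excluded from
    the direction terms and counted.
    """
    omega_hat = np.asarray(omega_hat, dtype=float)
    omega = np.asarray(omega, dtype=float)
    if omega_hat.shape != omega.shape:
        raise ValidationError("angular-velocity series must have equal shapes")
    keep = np.asarray(gold_speed) >= min_gold_speed
    if not keep.any():
        raise ValidationError("no samples at or above the gold-speed threshold")
    out, both = _direction_metrics(omega_hat, omega, keep, "AVDE")
    out["AVME"] = float(np.degrees(np.mean(
        np.linalg.norm(omega_hat[keep], axis=1) - np.linalg.norm(omega[keep], axis=1)
    )))
    out["n_used"] = int(both.sum())
    out["n_excluded"] = int(len(omega) - both.sum())
    return out
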