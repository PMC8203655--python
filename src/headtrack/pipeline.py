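"""End-to-end evaluation: sync → resample → register → calibrate → metrics → stats.

The stage order is fixed:

1. estimate the device clock offset (angular-velocity cross-correlation
   against the pose gold standard, or accelerometer tap matching against
   the wheel IMU) and shift the device timestamps;
2. resample the device stream onto the gold-standard timestamps;
3. estimate the world registration Ŵ→W and both calibrated body frames
   over the first 30 s of the task;
4. derive kinematics for both streams on the shared gold grid (so both
   are differentiated identically);
5. evaluate the metric suite;
6. pool per-cell metric values into condition tables for the
   repeated-measures statistics.

Cells with a pose gold standard produce the full metric suite; wheel
cells produce only trajectory-length and speed errors (the wheel
measures neither orientation nor 3-D position). Every threshold-based
exclusion is logged with counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import alignment, kinematics, metrics, quat
from .io_model import (
    KinematicTrajectory,
    MetricEntry,
    MetricReport,
    PoseTrajectory,
    RunConfig,
)
from .perambulator import wheel_speed_pipeline, wheel_trajectory_length
from .synthetic import SimulatedPair

logger = logging.getLogger(__name__)

__all__ = ["CellResult", "evaluate_ots_cell", "evaluate_wheel_cell",
           "run_evaluation", "metric_table", "pooled_statistics"]

METRIC_UNITS = {
    "TLE": "%", "ATE": "m", "RTE": "m", "TDr": "%", "TDr_rate": "m/h",
    "GDE": "deg", "GDE_alpha": "deg", "GDE_beta": "deg",
    "AYE": "deg", "RYE": "deg", "YDr": "deg/h",
    "SpE": "%", "HDE": "deg", "HDE_theta": "deg", "HDE_phi": "deg",
    "LVME": "m/s", "AVDE": "deg", "AVDE_theta": "deg", "AVDE_phi": "deg",
    "AVME": "deg/s", "L": "m", "L_hat": "m", "T": "s",
}


@dataclass
class CellResult:
    report: MetricReport | None
    sync: alignment.SyncResult | None = None
    frame_tree: alignment.FrameTree | None = None
    error: str | None = None
    diagnostics: dict = field(default_factory=dict)

    @property
    def failed(self) -> bool:
        return self.error is not None


def _body_vectors(pose: PoseTrajectory, kin: KinematicTrajectory):
    """Per-sample body-frame linear velocity and gravity direction."""
    qc = quat.qconj(pose.q)
    v_body = quat.rotate_vector(qc, kin.v)
    g_body = quat.rotate_vector(qc, kinematics.DOWN)
    return v_body, g_body


def evaluate_ots_cell(device: PoseTrajectory, gold: PoseTrajectory,
                      sync_end: float, config: RunConfig | None = None) -> CellResult:
    """Full metric suite for a device stream against a pose gold standard.

    ``sync_end`` is the gold-clock time at which the locomotion task
    starts (the preceding nod/shake segment is used for synchronization
    only; all metrics are computed over the task portion).
    """
    cfg = config or RunConfig()
    k = cfg.window_samples

    # --- 1. time synchronization on the nod/shake segment
    margin = 2.0
    dev_sync = device.slice_time(device.t[0], device.t[0] + sync_end + margin)
    gold_sync = gold.slice_time(gold.t[0], gold.t[0] + sync_end + margin)
    sync = alignment.estimate_time_offset(
        kinematics.derive_kinematics(dev_sync),
        kinematics.derive_kinematics(gold_sync),
        max_lag=cfg.max_lag,
    )
    device = device.shifted(-sync.delta_t)

    # --- 2. resample device onto gold timestamps (task portion)
    t0 = max(gold.t[0], device.t[0]) + 1e-9
    t1 = min(gold.t[-1], device.t[-1]) - 1e-9
    task_mask = (gold.t >= max(sync_end, t0)) & (gold.t <= t1)
    if task_mask.sum() <= k + 2:
        raise ValueError("task segment too short for the metric windows")
    gold_task = PoseTrajectory(gold.t[task_mask], gold.p[task_mask],
                               gold.q[task_mask], gold.frame_id)
    dev_task = alignment.resample_to(device, gold_task.t)

    # --- 3. world registration over the first calibration window of the task
    win = gold_task.t <= gold_task.t[0] + cfg.calibration_window
    world = alignment.register_world_frame(dev_task.p[win], gold_task.p[win])
    dev_w = PoseTrajectory(dev_task.t, world.apply_points(dev_task.p),
                           world.apply_orientations(dev_task.q), "W")

    # --- 4. kinematics on the shared grid
    kin_dev = kinematics.derive_kinematics(dev_w)
    kin_gold = kinematics.derive_kinematics(gold_task)
    v_body_dev, g_body_dev = _body_vectors(dev_w, kin_dev)
    v_body_gold, g_body_gold = _body_vectors(gold_task, kin_gold)
    speed_gold = kinematics.horizontal_speed(kin_gold)
    speed_dev = kinematics.horizontal_speed(kin_dev)

    # --- calibrated frames from the same window, slow samples excluded
    moving = win & (speed_gold.v >= cfg.speed_exclusion_threshold)
    cal_dev = alignment.estimate_calibrated_frame(
        v_body_dev[moving], g_body_dev[moving], "B_hat", "C_hat"
    )
    v_dev_cal = cal_dev.apply_vectors(v_body_dev)
    g_dev_cal = cal_dev.apply_vectors(g_body_dev)
    cal_gold = alignment.calibrate_gold_to_device(
        v_body_gold[moving], g_body_gold[moving],
        v_dev_cal[moving], g_dev_cal[moving], "B", "C",
    )
    v_gold_cal = cal_gold.apply_vectors(v_body_gold)
    g_gold_cal = cal_gold.apply_vectors(g_body_gold)
    omega_dev_cal = cal_dev.apply_vectors(kin_dev.omega)
    omega_gold_cal = cal_gold.apply_vectors(kin_gold.omega)

    tree = alignment.FrameTree(estimation_window=cfg.calibration_window)
    tree.add(world)
    tree.add(cal_dev)
    tree.add(cal_gold)

    # --- 5. metric suite
    t = gold_task.t
    duration = float(t[-1] - t[0])
    entries = []

    def add(name, value, n_used=0, n_excluded=0):
        entries.append(MetricEntry(name, float(value), METRIC_UNITS[name],
                                   int(n_used), int(n_excluded)))

    L, _ = metrics.trajectory_length(gold_task.p, t, cfg.artifact_speed_threshold)
    L_hat, n_art = metrics.trajectory_length(dev_w.p, t, cfg.artifact_speed_threshold)
    if n_art:
        logger.info("trajectory length: excluded %d artifact pairs (> %.1f m/s)",
                    n_art, cfg.artifact_speed_threshold)
    add("L", L, len(t))
    add("L_hat", L_hat, len(t) - 1 - n_art, n_art)
    add("TLE", metrics.tle(L_hat, L), len(t) - 1 - n_art, n_art)

    tm = metrics.translation_metrics(dev_w.p, gold_task.p, dev_w.q, gold_task.q,
                                     k=k, t=t, L=L,
                                     artifact_speed=cfg.artifact_speed_threshold)
    for name in ("ATE", "RTE", "TDr", "TDr_rate"):
        add(name, tm[name], len(t))

    delta_gamma = kinematics.yaw_difference(dev_w.q, gold_task.q)
    ym = metrics.yaw_metrics(delta_gamma, t, k=k,
                             percentile_bounds=cfg.percentile_bounds)
    logger.info("yaw metrics: %d used, %d percentile-excluded",
                ym["n_used"], ym["n_excluded"])
    for name in ("AYE", "RYE", "YDr"):
        add(name, ym[name], ym["n_used"], ym["n_excluded"])

    gm = metrics.gravity_metrics(g_dev_cal, g_gold_cal)
    for name in ("GDE", "GDE_alpha", "GDE_beta"):
        add(name, gm[name], gm["n_used"])

    sp = metrics.speed_error(speed_dev.v, speed_gold.v, cfg.speed_exclusion_threshold)
    logger.info("speed error: %d used, %d below %.2f m/s",
                sp["n_used"], sp["n_excluded"], cfg.speed_exclusion_threshold)
    add("SpE", sp["SpE"], sp["n_used"], sp["n_excluded"])

    lv = metrics.linear_velocity_metrics(v_dev_cal, v_gold_cal, speed_gold.v,
                                         cfg.speed_exclusion_threshold)
    for name in ("HDE", "HDE_theta", "HDE_phi", "LVME"):
        add(name, lv[name], lv["n_used"], lv["n_excluded"])

    av = metrics.angular_velocity_metrics(omega_dev_cal, omega_gold_cal,
                                          speed_gold.v, cfg.speed_exclusion_threshold)
    for name in ("AVDE", "AVDE_theta", "AVDE_phi", "AVME"):
        add(name, av[name], av["n_used"], av["n_excluded"])

    add("T", duration, len(t))
    report = MetricReport(entries, duration=duration)
    return CellResult(report, sync=sync, frame_tree=tree)


def evaluate_wheel_cell(device: PoseTrajectory, wheel, device_imu, wheel_imu,
                        config: RunConfig | None = None) -> CellResult:
    """Trajectory-length and speed errors against the surveyor wheel.

    The wheel provides no pose, so no world registration is possible; the
    device world frame is taken as gravity-aligned (its z axis vertical),
    which the device establishes internally from its IMU.
    """
    cfg = config or RunConfig()
    offset = alignment.tap_offset_from_accel(device_imu, wheel_imu)
    device = device.shifted(-offset)

    cleaned = wheel_speed_pipeline(
        wheel, cfg.wheel_cutoff_hz, cfg.min_wheel_speed, cfg.min_wheel_segment
    )
    logger.info("wheel cleaning: %d samples excluded", cleaned.excluded_count)
    if len(cleaned) == 0:
        raise ValueError("wheel speed series empty after cleaning")

    kin_dev = kinematics.derive_kinematics(device)
    speed_dev = kinematics.horizontal_speed(kin_dev)
    in_span = (cleaned.t >= device.t[0]) & (cleaned.t <= device.t[-1])
    v_gold = cleaned.v[in_span]
    v_dev = np.interp(cleaned.t[in_span], speed_dev.t, speed_dev.v)

    sp = metrics.speed_error(v_dev, v_gold, cfg.speed_exclusion_threshold)
    L = wheel_trajectory_length(wheel)
    L_hat, n_art = metrics.trajectory_length(device.p, device.t,
                                             cfg.artifact_speed_threshold)
    entries = [
        MetricEntry("L", L, "m"),
        MetricEntry("L_hat", float(L_hat), "m", n_excluded=n_art),
        MetricEntry("TLE", metrics.tle(L_hat, L), "%", n_excluded=n_art),
        MetricEntry("SpE", sp["SpE"], "%", sp["n_used"], sp["n_excluded"]),
    ]
    duration = float(device.t[-1] - device.t[0])
    report = MetricReport(entries, duration=duration)
    result = CellResult(report)
    result.diagnostics["tap_offset"] = offset
    return result


def evaluate_pair(pair: SimulatedPair, config: RunConfig | None = None) -> CellResult:
    """Evaluate one simulated cell with the gold standard it carries."""
    if pair.gold_kind == "wheel":
        result = evaluate_wheel_cell(pair.device, pair.wheel,
                                     pair.device_imu, pair.wheel_imu, config)
    else:
        result = evaluate_ots_cell(pair.device, pair.gold, pair.sync_end, config)
    rep = result.report
    rep.subject, rep.task, rep.environment = pair.subject, pair.task, pair.environment
    return result


def run_evaluation(pairs, config: RunConfig | None = None):
    """Evaluate a batch of cells; failures are recorded, the batch continues.

    Returns ``(results, reports)`` where ``reports`` collects the
    successful cells' metric reports.
    """
    results = []
    reports = []
    for pair in pairs:
        label = (pair.subject, pair.task, pair.environment)
        try:
            res = evaluate_pair(pair, config)
        except Exception as exc:  # noqa: BLE001 - cell isolation is the contract
            logger.warning("cell %s failed: %s", label, exc)
            res = CellResult(None, error=f"{type(exc).__name__}: {exc}")
        results.append(res)
        if not res.failed:
            reports.append(res.report)
    return results, reports


def metric_table(reports) -> pd.DataFrame:
    """Long-format DataFrame of all metric values across cells."""
    rows = []
    for rep in reports:
        for e in rep.entries:
            rows.append({
                "subject": rep.subject, "task": rep.task,
                "environment": rep.environment, "metric": e.name,
                "value": e.value, "units": e.units,
                "n_used": e.n_used, "n_excluded": e.n_excluded,
            })
    return pd.DataFrame(rows)


def pooled_statistics(reports, metric: str, factor: str = "task",
                      second_factor: str | None = None, alpha: float = 0.05):
    """Repeated-measures ANOVA (+ post-hoc) of one metric across conditions.

    Builds the complete subject × condition table for ``metric`` and runs
    the one-way (or, with ``second_factor``, two-way) within-subject
    ANOVA; Bonferroni-halved paired t-tests follow for significant
    effects.
    """
    from . import stats_summary

    df = metric_table(reports)
    df = df[df.metric == metric]
    if second_factor is None:
        wide = df.pivot_table(index="subject", columns=factor, values="value")
        if wide.isna().any().any():
            raise ValueError("unbalanced design: missing cells")
        res = stats_summary.rm_anova(wide.to_numpy(), "one-way")["condition"]
        if res.p < alpha:
            res.posthoc = stats_summary.posthoc_paired_t(
                wide.to_numpy(), labels=list(wide.columns), alpha=alpha
            )
        return res
    cube = df.pivot_table(index="subject", columns=[factor, second_factor],
                          values="value")
    if cube.isna().any().any():
        raise ValueError("unbalanced design: missing cells")
    levels_a = cube.columns.get_level_values(0).unique()
    levels_b = cube.columns.get_level_values(1).unique()
    arr = np.stack(
        [np.stack([cube[(a, b)].to_numpy() for b in levels_b], axis=1) for a in levels_a],
        axis=1,
    )
    out = stats_summary.rm_anova(arr, "two-way")
    from . import stats_summary as ss
    for key, axis_levels, axis in (("A", levels_a, 1), ("B", levels_b, 2)):
        if out[key].p < alpha:
            collapsed = arr.mean(axis=3 - axis)
            out[key].posthoc = ss.posthoc_paired_t(
                collapsed, labels=list(axis_levels), alpha=alpha
            )
    return out
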