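"""Core record types, file readers/writers and run configuration.

Streams are stored on disk as plain CSV with a small JSON sidecar
(``<file>.json``) carrying metadata that does not fit a flat table
(frame label, wheel circumference, counter reading). Time stamps are
seconds as floating point relative to stream start.

Frame labels follow the evaluation's reference-frame tree: the optical
gold standard lives in world frame ``W`` with body frame ``B`` and
calibrated body frame ``C``; the device under test reports in its own
world frame ``W_hat`` with body frame ``B_hat`` and calibrated frame
``C_hat``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import yaml

from . import quat

FRAME_LABELS = ("W", "W_hat", "B", "B_hat", "C", "C_hat")

POSE_COLUMNS = ["t", "px", "py", "pz", "qw", "qx", "qy", "qz"]
IMU_COLUMNS = ["t", "ax", "ay", "az", "gx", "gy", "gz"]
WHEEL_COLUMNS = ["t", "omega_p"]
REPORT_COLUMNS = [
    "subject",
    "environment",
    "task",
    "metric",
    "value",
    "units",
    "n_used",
    "n_excluded",
]


class FormatError(ValueError):
    """A file does not have the expected columns or structure."""


class ValidationError(ValueError):
    """A record violates one of its invariants."""


def _check_monotonic(t: np.ndarray) -> None:
    dt = np.diff(t)
    bad = np.nonzero(dt <= 0)[0]
    if bad.size:
        raise ValidationError(
            f"time stamps not strictly increasing: first offense at index {bad[0] + 1}"
        )


def _check_finite(name: str, x: np.ndarray) -> None:
    if not np.all(np.isfinite(x)):
        raise ValidationError(f"{name} contains non-finite values")


@dataclass
class PoseTrajectory:
    """Timestamped 6-DOF pose stream: positions and unit quaternions.

    Attributes
    ----------
    t : (n,) seconds, strictly increasing
    p : (n, 3) position in metres
    q : (n, 4) scalar-first unit quaternions (body → world of ``frame_id``)
    frame_id : one of ``FRAME_LABELS``
    """

    t: np.ndarray
    p: np.ndarray
    q: np.ndarray
    frame_id: str = "W"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.p = np.asarray(self.p, dtype=float).reshape(-1, 3)
        self.q = np.asarray(self.q, dtype=float).reshape(-1, 4)
        if not (len(self.t) == len(self.p) == len(self.q)):
            raise ValidationError("t, p and q must have equal lengths")
        if self.frame_id not in FRAME_LABELS:
            raise ValidationError(f"unknown frame label {self.frame_id!r}")
        _check_monotonic(self.t)
        _check_finite("position", self.p)
        _check_finite("quaternion", self.q)
        norms = np.linalg.norm(self.q, axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValidationError("quaternions deviate from unit norm by more than 1e-6")
        if np.any(np.abs(norms - 1.0) > 1e-9):
            self.q = self.q / norms[:, None]

    def __len__(self) -> int:
        return len(self.t)

    def slice_time(self, t0: float, t1: float) -> "PoseTrajectory":
        m = (self.t >= t0) & (self.t <= t1)
        return PoseTrajectory(self.t[m], self.p[m], self.q[m], self.frame_id)

    def shifted(self, dt: float) -> "PoseTrajectory":
        return PoseTrajectory(self.t + dt, self.p, self.q, self.frame_id)


@dataclass
class KinematicTrajectory:
    """Derived linear velocity v (m/s) and angular velocity omega (rad/s)."""

    t: np.ndarray
    v: np.ndarray
    omega: np.ndarray
    frame_id: str = "W"

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float).reshape(-1, 3)
        self.omega = np.asarray(self.omega, dtype=float).reshape(-1, 3)
        if not (len(self.t) == len(self.v) == len(self.omega)):
            raise ValidationError("t, v and omega must have equal lengths")
        _check_monotonic(self.t)
        _check_finite("velocity", self.v)
        _check_finite("angular velocity", self.omega)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class ImuTrajectory:
    """6-axis IMU stream: accelerometer (m/s²) and gyroscope (rad/s)."""

    t: np.ndarray
    accel: np.ndarray
    gyro: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.accel = np.asarray(self.accel, dtype=float).reshape(-1, 3)
        self.gyro = np.asarray(self.gyro, dtype=float).reshape(-1, 3)
        _check_monotonic(self.t)
        _check_finite("accelerometer", self.accel)
        _check_finite("gyroscope", self.gyro)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class WheelRecording:
    """Surveyor-wheel stream: axle angular rate plus the distance counter.

    ``omega_p`` is in revolutions per second (sensors reporting °/s are
    divided by 360 on ingest), so speed = circumference × omega_p.
    """

    t: np.ndarray
    omega_p: np.ndarray
    counter_distance: float
    circumference: float = 1.0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.omega_p = np.asarray(self.omega_p, dtype=float).reshape(-1)
        if self.circumference <= 0:
            raise ValidationError("wheel circumference must be positive")
        if self.counter_distance is not None and self.counter_distance < 0:
            raise ValidationError("counter distance cannot be negative")
        _check_monotonic(self.t)
        _check_finite("wheel rate", self.omega_p)

    def __len__(self) -> int:
        return len(self.t)


@dataclass
class RunConfig:
    """Evaluation constants; defaults are the study's published choices."""

    window_samples: int = 50          # k: RTE/RYE window (≈1 s at 50 Hz)
    speed_exclusion_threshold: float = 0.1   # m/s, dagger rule
    artifact_speed_threshold: float = 5.0    # m/s, re-localization artifacts
    calibration_window: float = 30.0         # s, frame estimation window
    kde_bandwidth: float = 0.2               # m/s, speed KDE bandwidth h
    percentile_bounds: tuple = (1.0, 99.0)   # Δγ outlier exclusion
    wheel_cutoff_hz: float = 10.0            # Butterworth low-pass cutoff
    min_wheel_speed: float = 0.01            # m/s, wheel cleaning threshold
    min_wheel_segment: float = 3.0           # s, wheel cleaning min segment
    max_lag: float = 10.0                    # s, sync search range
    rates: dict = field(default_factory=lambda: {
        "device_pose": 200.0, "device_imu": 62.5,
        "gold_pose": 50.0, "wheel_imu": 100.0,
    })
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window_samples < 1:
            raise ValidationError("window_samples must be >= 1")
        for name in ("speed_exclusion_threshold", "artifact_speed_threshold",
                     "calibration_window", "kde_bandwidth", "wheel_cutoff_hz",
                     "min_wheel_speed", "min_wheel_segment", "max_lag"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        lo, hi = self.percentile_bounds
        if not (0 <= lo < hi < 100):
            raise ValidationError("percentile bounds must satisfy 0 <= lo < hi < 100")
        self.percentile_bounds = (float(lo), float(hi))
        for k, v in self.rates.items():
            if v <= 0:
                raise ValidationError(f"rate {k!r} must be positive")


@dataclass
class MetricEntry:
    name: str
    value: float
    units: str
    n_used: int = 0
    n_excluded: int = 0


@dataclass
class MetricReport:
    """Named error metrics for one (subject, task, environment) cell."""

    entries: list
    subject: str = ""
    task: str = ""
    environment: str = ""
    duration: float = 0.0

    def as_dict(self) -> dict:
        return {e.name: e.value for e in self.entries}

    def __getitem__(self, name: str) -> float:
        for e in self.entries:
            if e.name == name:
                return e.value
        raise KeyError(name)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def _sidecar_path(path) -> Path:
    path = Path(path)
    return path.with_suffix(path.suffix + ".json")


def _read_csv(path, columns: Iterable[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_pose_trajectory(path, frame_id: str | None = None) -> PoseTrajectory:
    """Read a pose CSV (``t,px,py,pz,qw,qx,qy,qz``) plus optional sidecar."""
    df = _read_csv(path, POSE_COLUMNS)
    if frame_id is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            frame_id = json.loads(sidecar.read_text()).get("frame_id", "W")
        else:
            frame_id = "W"
    return PoseTrajectory(
        df["t"].to_numpy(),
        df[["px", "py", "pz"]].to_numpy(),
        df[["qw", "qx", "qy", "qz"]].to_numpy(),
        frame_id,
    )


def write_pose_trajectory(traj: PoseTrajectory, path) -> None:
    df = pd.DataFrame(
        np.column_stack([traj.t, traj.p, traj.q]), columns=POSE_COLUMNS
    )
    df.to_csv(path, index=False, float_format="%.12g")
    _sidecar_path(path).write_text(json.dumps({"frame_id": traj.frame_id}))


def read_imu_trajectory(path) -> ImuTrajectory:
    df = _read_csv(path, IMU_COLUMNS)
    return ImuTrajectory(
        df["t"].to_numpy(),
        df[["ax", "ay", "az"]].to_numpy(),
        df[["gx", "gy", "gz"]].to_numpy(),
    )


def write_imu_trajectory(imu: ImuTrajectory, path) -> None:
    df = pd.DataFrame(np.column_stack([imu.t, imu.accel, imu.gyro]), columns=IMU_COLUMNS)
    df.to_csv(path, index=False, float_format="%.12g")


def read_wheel_recording(path) -> WheelRecording:
    df = _read_csv(path, WHEEL_COLUMNS)
    sidecar = _sidecar_path(path)
    meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return WheelRecording(
        df["t"].to_numpy(),
        df["omega_p"].to_numpy(),
        counter_distance=meta.get("counter_distance"),
        circumference=meta.get("circumference", 1.0),
    )


def write_wheel_recording(rec: WheelRecording, path) -> None:
    pd.DataFrame({"t": rec.t, "omega_p": rec.omega_p}).to_csv(
        path, index=False, float_format="%.12g"
    )
    _sidecar_path(path).write_text(
        json.dumps(
            {"circumference": rec.circumference, "counter_distance": rec.counter_distance}
        )
    )


def write_metric_report(reports, path) -> None:
    """Write one or more reports as a long-format CSV table."""
    if isinstance(reports, MetricReport):
        reports = [reports]
    rows = []
    for rep in reports:
        for e in rep.entries:
            rows.append(
                {
                    "subject": rep.subject,
                    "environment": rep.environment,
                    "task": rep.task,
                    "metric": e.name,
                    "value": e.value,
                    "units": e.units,
                    "n_used": e.n_used,
                    "n_excluded": e.n_excluded,
                }
            )
    if not rows:
        raise ValidationError("cannot write an empty metric report")
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, index=False, float_format="%.12g")


def read_metric_report(path) -> pd.DataFrame:
    return _read_csv(path, REPORT_COLUMNS)


_CONFIG_ALIASES = {"k": "window_samples", "h": "kde_bandwidth"}


def load_config(path_or_dict) -> RunConfig:
    """Load a JSON/YAML run configuration; missing fields take study defaults."""
    if isinstance(path_or_dict, dict):
        doc = dict(path_or_dict)
    else:
        text = Path(path_or_dict).read_text()
        doc = yaml.safe_load(text) or {}
        if not isinstance(doc, dict):
            raise FormatError("config document must be a mapping")
    doc = {_CONFIG_ALIASES.get(k, k): v for k, v in doc.items()}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(doc) - known
    if unknown:
        raise FormatError(f"unknown config field(s): {sorted(unknown)}")
    if "percentile_bounds" in doc:
        doc["percentile_bounds"] = tuple(doc["percentile_bounds"])
    base = RunConfig()
    if "rates" in doc:
        merged = dict(base.rates)
        merged.update(doc["rates"])
        doc["rates"] = merged
    return dataclasses.replace(base, **doc)
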