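"""Synthetic head-motion and tracker-error simulator.

Generates the inputs the evaluation pipeline expects without any
recorded data: a ground-truth head trajectory walking laps around a
rounded-rectangle circuit at a task speed (slow walk / walk / run), with
gait oscillations (vertical bob, yaw/pitch/roll sway at step frequency)
and an initial synchronization segment of slow nods and shakes; a
"device" stream derived from the truth by injecting the error phenomena
a visual-inertial tracker exhibits (scale misestimation, yaw drift,
additive noise, re-localization jumps, an unknown clock offset, and
unknown world-frame and head-mount rotations); and a surveyor-wheel
recording derived from the truth ground speed.

The gait model is a deterministic oscillation, not a biomechanical
simulation — sufficient to exercise differentiation, synchronization,
frame calibration and the metric suite. Error injection order is fixed:
scale → yaw drift → noise → jumps → resample → clock offset → world
frame → mount rotation, so that recovery experiments are well-posed.

Every operation is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import quat
from .io_model import ImuTrajectory, PoseTrajectory, ValidationError, WheelRecording
from .kinematics import SpeedSeries, derive_kinematics, horizontal_speed

__all__ = [
    "CircuitConfig",
    "GaitConfig",
    "SyncSegmentConfig",
    "ErrorModel",
    "SimulationConfig",
    "SimulatedPair",
    "simulate_truth",
    "corrupt_to_device",
    "simulate_wheel",
    "simulate_tap_imu",
    "generate_study",
    "TASK_SPEEDS",
    "ENVIRONMENTS",
]

# Median self-chosen speeds reported for the three locomotion tasks fall
# in 0.7-1.2 (slow walk), 1.0-1.5 (walk) and 1.7-2.6 m/s (run); the
# defaults sit inside those ranges.
TASK_SPEEDS = {"slow_walk": 0.9, "walk": 1.4, "run": 2.2}


@dataclass
class CircuitConfig:
    """Rounded-rectangle walking circuit (metres)."""

    width: float = 12.0
    height: float = 8.0
    corner_radius: float = 2.0
    laps: float = 2.0
    direction: int = 1          # +1 counterclockwise, -1 clockwise
    head_height: float = 1.6

    @property
    def perimeter(self) -> float:
        w, h, r = self.width, self.height, self.corner_radius
        if w < 2 * r or h < 2 * r:
            raise ValidationError("corner radius too large for rectangle dimensions")
        return 2.0 * (w - 2 * r) + 2.0 * (h - 2 * r) + 2.0 * np.pi * r


@dataclass
class GaitConfig:
    """Deterministic gait oscillations superimposed on the circuit path."""

    step_frequency: float = 2.0     # Hz
    bob_amplitude: float = 0.03     # m, vertical head bob
    yaw_sway: float = 5.0           # deg
    pitch_sway: float = 3.0         # deg
    roll_sway: float = 2.0          # deg


@dataclass
class SyncSegmentConfig:
    """Initial stationary nod/shake segment used for time synchronization."""

    nods: int = 5
    shakes: int = 5
    amplitude: float = 20.0         # deg
    rate: float = 0.5               # Hz (cycles per second)
    lead_in: float = 1.0            # s of stillness before and after


@dataclass
class ErrorModel:
    """Tracker error phenomena injected into the device stream.

    The default-constructed model is the identity: the device stream
    then reproduces the truth exactly (up to resampling).
    """

    scale_factor: float = 1.0           # unitless, applied about the start point
    yaw_drift_rate: float = 0.0         # deg/h, accumulating rotation about z
    position_noise_sd: float = 0.0      # m, additive band-limited noise
    orientation_noise_sd: float = 0.0   # deg, band-limited random rotations
    noise_bandwidth: float = 1.0        # Hz, low-pass corner of the noise
                                        # (tracker output is smooth, not white)
    reloc_per_minute: float = 0.0       # Poisson rate of re-localization jumps
    reloc_jump_size: float = 1.0        # m, horizontal jump magnitude
    reloc_reversal: float = 0.0         # fraction of accumulated offset undone
    time_offset: float = 0.0            # s, device clock minus gold clock
    world_yaw: float = 0.0              # deg, world-frame rotation W_hat -> W
    world_rotvec: tuple = (0.0, 0.0, 0.0)   # deg, full 3-D world rotation (overrides yaw if nonzero)
    world_translation: tuple = (0.0, 0.0, 0.0)  # m
    mount_rotvec: tuple = (0.0, 0.0, 0.0)       # deg, head-mount rotation B -> B_hat

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise ValidationError("scale_factor must be positive")
        for name in ("position_noise_sd", "orientation_noise_sd", "reloc_per_minute"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} cannot be negative")

    def world_quat(self) -> np.ndarray:
        rv = np.radians(self.world_rotvec)
        if np.any(rv != 0):
            from scipy.spatial.transform import Rotation
            return quat.from_rotation(Rotation.from_rotvec(rv))
        return quat.from_axis_angle([0, 0, 1], np.radians(self.world_yaw))

    def mount_quat(self) -> np.ndarray:
        from scipy.spatial.transform import Rotation
        return quat.from_rotation(Rotation.from_rotvec(np.radians(self.mount_rotvec)))

    @property
    def is_identity(self) -> bool:
        return (
            self.scale_factor == 1.0 and self.yaw_drift_rate == 0.0
            and self.position_noise_sd == 0.0 and self.orientation_noise_sd == 0.0
            and self.reloc_per_minute == 0.0 and self.time_offset == 0.0
            and self.world_yaw == 0.0 and not np.any(np.asarray(self.world_rotvec))
            and not np.any(np.asarray(self.world_translation))
            and not np.any(np.asarray(self.mount_rotvec))
        )


@dataclass
class SimulationConfig:
    circuit: CircuitConfig = field(default_factory=CircuitConfig)
    gait: GaitConfig = field(default_factory=GaitConfig)
    sync: SyncSegmentConfig = field(default_factory=SyncSegmentConfig)
    error_model: ErrorModel = field(default_factory=ErrorModel)
    speed: float = TASK_SPEEDS["walk"]      # m/s along the circuit
    rates: dict = field(default_factory=lambda: {
        "device_pose": 200.0, "device_imu": 62.5,
        "gold_pose": 50.0, "wheel_imu": 100.0,
    })
    seed: int = 0

    def __post_init__(self):
        if self.speed <= 0:
            raise ValidationError("speed must be positive")
        for k, v in self.rates.items():
            if v <= 0:
                raise ValidationError(f"rate {k!r} must be positive")


@dataclass
class SimulatedPair:
    """One simulated recording cell: truth, gold standard, device, wheel."""

    truth: PoseTrajectory               # frame W, device-rate grid
    gold: PoseTrajectory                # frame W, gold-rate subsample
    device: PoseTrajectory              # frame W_hat, device clock
    injected: ErrorModel
    sync_end: float
    wheel: WheelRecording | None = None
    device_imu: ImuTrajectory | None = None
    wheel_imu: ImuTrajectory | None = None
    subject: str = ""
    task: str = ""
    environment: str = ""
    gold_kind: str = "ots"


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------

def _rounded_rect(s: np.ndarray, circ: CircuitConfig):
    """Position (x, y) and tangent angle ψ at arclength s along the circuit."""
    w, h, r = circ.width, circ.height, circ.corner_radius
    lw, lh = w - 2 * r, h - 2 * r
    arc = np.pi * r / 2.0
    lengths = np.array([lw, arc, lh, arc, lw, arc, lh, arc])
    bounds = np.concatenate([[0.0], np.cumsum(lengths)])
    p = bounds[-1]
    s = np.mod(s, p)
    seg = np.clip(np.searchsorted(bounds, s, side="right") - 1, 0, 7)
    u = s - bounds[seg]
    hw, hh = w / 2.0, h / 2.0
    x = np.empty_like(s)
    y = np.empty_like(s)
    psi = np.empty_like(s)
    # straights: bottom (+x), right (+y), top (-x), left (-y)
    for i, (x0, y0, dx, dy, ang) in enumerate([
        (-lw / 2.0, -hh, 1.0, 0.0, 0.0),
        (hw, -lh / 2.0, 0.0, 1.0, np.pi / 2.0),
        (lw / 2.0, hh, -1.0, 0.0, np.pi),
        (-hw, lh / 2.0, 0.0, -1.0, -np.pi / 2.0),
    ]):
        m = seg == 2 * i
        x[m] = x0 + dx * u[m]
        y[m] = y0 + dy * u[m]
        psi[m] = ang
    # corner arcs, counterclockwise quarter circles
    for i, (cx, cy, phi0) in enumerate([
        (lw / 2.0, -lh / 2.0, -np.pi / 2.0),
        (lw / 2.0, lh / 2.0, 0.0),
        (-lw / 2.0, lh / 2.0, np.pi / 2.0),
        (-lw / 2.0, -lh / 2.0, np.pi),
    ]):
        m = seg == 2 * i + 1
        phi = phi0 + u[m] / r
        x[m] = cx + r * np.cos(phi)
        y[m] = cy + r * np.sin(phi)
        psi[m] = phi + np.pi / 2.0
    return x, y, psi


def _euler_zyx_quat(yaw, pitch, roll):
    """Body->world quaternion from intrinsic z-y-x (yaw, pitch, roll), radians."""
    qz = np.stack([np.cos(yaw / 2), 0 * yaw, 0 * yaw, np.sin(yaw / 2)], axis=-1)
    qy = np.stack([np.cos(pitch / 2), 0 * pitch, np.sin(pitch / 2), 0 * pitch], axis=-1)
    qx = np.stack([np.cos(roll / 2), np.sin(roll / 2), 0 * roll, 0 * roll], axis=-1)
    return quat.qmul(quat.qmul(qz, qy), qx)


def simulate_truth(config: SimulationConfig):
    """Ground-truth head trajectory: sync segment followed by circuit laps.

    Returns ``(trajectory, sync_end)`` where the trajectory is sampled at
    the device pose rate in world frame W and ``sync_end`` is the time at
    which locomotion starts.
    """
    circ, gait, sync = config.circuit, config.gait, config.sync
    fs = config.rates["device_pose"]
    dt = 1.0 / fs
    t_nod = sync.nods / sync.rate
    t_shake = sync.shakes / sync.rate
    sync_end = sync.lead_in * 2.0 + t_nod + t_shake
    t_walk = circ.laps * circ.perimeter / config.speed
    n = int(round((sync_end + t_walk) * fs)) + 1
    t = np.arange(n) * dt

    walk = t >= sync_end
    s = np.where(walk, config.speed * (t - sync_end), 0.0)
    if circ.direction < 0:
        s = -s
    x, y, psi = _rounded_rect(s, circ)
    if circ.direction < 0:
        # traverse clockwise: mirror the parametrization direction
        psi = psi + np.pi
    amp = np.radians(sync.amplitude)
    phase = 2.0 * np.pi * sync.rate
    pitch = np.zeros(n)
    yaw_off = np.zeros(n)
    nodding = (t >= sync.lead_in) & (t < sync.lead_in + t_nod)
    shaking = (t >= sync.lead_in + t_nod) & (t < sync.lead_in + t_nod + t_shake)
    pitch[nodding] = amp * np.sin(phase * (t[nodding] - sync.lead_in))
    yaw_off[shaking] = amp * np.sin(phase * (t[shaking] - sync.lead_in - t_nod))

    wg = 2.0 * np.pi * gait.step_frequency
    tw = np.where(walk, t - sync_end, 0.0)
    bob = np.where(walk, gait.bob_amplitude * np.sin(wg * tw), 0.0)
    yaw_off = yaw_off + np.where(walk, np.radians(gait.yaw_sway) * np.sin(wg * tw / 2.0), 0.0)
    pitch = pitch + np.where(walk, np.radians(gait.pitch_sway) * np.sin(wg * tw), 0.0)
    roll = np.where(walk, np.radians(gait.roll_sway) * np.sin(wg * tw / 2.0 + np.pi / 3), 0.0)

    p = np.column_stack([x, y, circ.head_height + bob])
    q = quat.qnormalize(_euler_zyx_quat(psi + yaw_off, pitch, roll))
    return PoseTrajectory(t, p, q, "W"), float(sync_end)


def subsample_gold(truth: PoseTrajectory, device_rate: float, gold_rate: float) -> PoseTrajectory:
    """Gold-standard pose stream: the truth on the (coarser) gold grid."""
    step = device_rate / gold_rate
    if abs(step - round(step)) < 1e-9:
        idx = np.arange(0, len(truth), int(round(step)))
        return PoseTrajectory(truth.t[idx], truth.p[idx], truth.q[idx], "W")
    from .alignment import resample_to
    target = np.arange(truth.t[0], truth.t[-1] + 1e-9, 1.0 / gold_rate)
    return resample_to(truth, target[target <= truth.t[-1]])


# ---------------------------------------------------------------------------
# device corruption
# ---------------------------------------------------------------------------

def _band_limited_noise(rng, shape, fs: float, bandwidth: float, sd: float) -> np.ndarray:
    """Gaussian noise low-passed to ``bandwidth`` Hz, rescaled to sd."""
    white = rng.normal(0.0, 1.0, shape)
    if bandwidth >= 0.45 * fs:
        return sd * white
    from scipy.signal import butter, filtfilt
    b, a = butter(2, bandwidth / (fs / 2.0), btype="low")
    smooth = filtfilt(b, a, white, axis=0)
    scale = smooth.std(axis=0, keepdims=True)
    scale[scale == 0] = 1.0
    return sd * smooth / scale

def corrupt_to_device(truth: PoseTrajectory, error_model: ErrorModel,
                      seed: int = 0, device_rate: float | None = None) -> PoseTrajectory:
    """Apply the tracker error model to the truth, yielding the device stream.

    Injection order: scale about the start point → accumulating yaw
    drift → additive position/orientation noise → Poisson-timed
    re-localization jumps → resampling to the device rate → clock offset
    → expression in the device world frame Ŵ → head-mount rotation of
    the body frame (B → B̂).
    """
    rng = np.random.default_rng(seed)
    t = truth.t.copy()
    p = truth.p.copy()
    q = truth.q.copy()
    p0 = p[0].copy()

    if error_model.scale_factor != 1.0:
        p = p0 + error_model.scale_factor * (p - p0)

    if error_model.yaw_drift_rate != 0.0:
        ang = np.radians(error_model.yaw_drift_rate) / 3600.0 * (t - t[0])
        qd = np.stack([np.cos(ang / 2), 0 * ang, 0 * ang, np.sin(ang / 2)], axis=-1)
        p = p0 + quat.rotate_vector(qd, p - p0)
        q = quat.qmul(qd, q)

    fs = 1.0 / np.median(np.diff(t))
    if error_model.position_noise_sd > 0:
        p = p + _band_limited_noise(
            rng, p.shape, fs, error_model.noise_bandwidth,
            error_model.position_noise_sd,
        )
    if error_model.orientation_noise_sd > 0:
        rv = _band_limited_noise(
            rng, (len(q), 3), fs, error_model.noise_bandwidth,
            np.radians(error_model.orientation_noise_sd),
        )
        q = quat.qmul(quat.qexp(rv / 2.0), q)

    if error_model.reloc_per_minute > 0:
        duration_min = (t[-1] - t[0]) / 60.0
        n_jumps = rng.poisson(error_model.reloc_per_minute * duration_min)
        accum = np.zeros(3)
        offsets = np.zeros_like(p)
        jump_times = np.sort(rng.uniform(t[0], t[-1], n_jumps))
        for tj in jump_times:
            direction = rng.normal(size=2)
            direction /= np.linalg.norm(direction)
            step = np.concatenate([error_model.reloc_jump_size * direction, [0.0]])
            step = (1.0 - error_model.reloc_reversal) * step \
                - error_model.reloc_reversal * accum
            accum = accum + step
            offsets[t >= tj] += step
        p = p + offsets

    if device_rate is not None:
        native = 1.0 / np.median(np.diff(t))
        if abs(native - device_rate) > 1e-6:
            from .alignment import resample_to
            target = np.arange(t[0], t[-1] + 1e-12, 1.0 / device_rate)
            target = target[target <= t[-1] + 1e-9]
            tmp = resample_to(PoseTrajectory(t, p, q, "W"), target)
            t, p, q = tmp.t, tmp.p, tmp.q

    t = t + error_model.time_offset

    r_w = error_model.world_quat()
    d_w = np.asarray(error_model.world_translation, dtype=float)
    r_w_inv = quat.qconj(r_w)
    p = quat.rotate_vector(r_w_inv, p - d_w)
    q = quat.qmul(r_w_inv, q)

    q = quat.qmul(q, error_model.mount_quat())
    return PoseTrajectory(t, p, quat.qnormalize(q), "W_hat")


# ---------------------------------------------------------------------------
# wheel and IMU streams
# ---------------------------------------------------------------------------

def simulate_wheel(truth_speed: SpeedSeries, circumference: float = 1.0,
                   noise_sd: float = 0.0, rate: float = 100.0,
                   seed: int = 0) -> WheelRecording:
    """Surveyor-wheel recording rolling at the truth ground speed.

    ``omega_p = v/C`` (rev/s) plus white noise at the wheel IMU rate;
    the distance counter integrates the truth speed.
    """
    if circumference <= 0:
        raise ValidationError("circumference must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(truth_speed.t[0], truth_speed.t[-1] + 1e-12, 1.0 / rate)
    t = t[t <= truth_speed.t[-1] + 1e-9]
    v = np.interp(t, truth_speed.t, truth_speed.v)
    omega = v / circumference
    if noise_sd > 0:
        omega = omega + rng.normal(0.0, noise_sd / circumference, omega.shape)
    counter = float(np.trapezoid(truth_speed.v, truth_speed.t))
    return WheelRecording(t, omega, counter_distance=counter, circumference=circumference)


def simulate_tap_imu(tap_time: float, duration: float, rate: float,
                     clock_offset: float = 0.0, noise_sd: float = 0.05,
                     tap_magnitude: float = 30.0, seed: int = 0) -> ImuTrajectory:
    """Accelerometer stream with a tap transient for tap synchronization.

    The tap occurs at ``tap_time`` on the reference clock and appears at
    ``tap_time + clock_offset`` on this stream's own timestamps.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration, 1.0 / rate) + clock_offset
    accel = np.tile([0.0, 0.0, 9.81], (len(t), 1))
    accel += rng.normal(0.0, noise_sd, accel.shape)
    local_tap = tap_time + clock_offset
    pulse = tap_magnitude * np.exp(-0.5 * ((t - local_tap) / 0.01) ** 2)
    accel[:, 0] += pulse
    gyro = rng.normal(0.0, 0.01, accel.shape)
    return ImuTrajectory(t, accel, gyro)


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

# Environments of increasing size. The optical tracking space provides a
# pose gold standard; the real-world circuits provide wheel odometry.
# Default scale factors shrink with environment size (scene landmarks
# recede, stereo disparity drops), so speed and length get progressively
# under-estimated, and drift/noise grow with task speed.
ENVIRONMENTS = {
    "tracking_space": dict(kind="ots", width=12.0, height=8.0, scale=1.01),
    "hallway": dict(kind="wheel", width=36.0, height=4.5, scale=0.99),
    "lobby": dict(kind="wheel", width=26.0, height=14.0, scale=0.965),
    "courtyard": dict(kind="wheel", width=55.0, height=25.0, scale=0.92),
}

_DRIFT_BY_TASK = {"slow_walk": 4.0, "walk": 10.0, "run": 25.0}      # deg/h
_NOISE_BY_TASK = {"slow_walk": 0.004, "walk": 0.006, "run": 0.012}  # m


def default_error_model(task: str, environment: str, rng) -> ErrorModel:
    env = ENVIRONMENTS[environment]
    return ErrorModel(
        scale_factor=env["scale"] * float(np.exp(rng.normal(0.0, 0.008))),
        yaw_drift_rate=_DRIFT_BY_TASK[task] * float(np.exp(rng.normal(0.0, 0.2))),
        position_noise_sd=_NOISE_BY_TASK[task],
        orientation_noise_sd=0.2,
        time_offset=float(rng.uniform(-0.5, 0.5)),
        world_yaw=float(rng.uniform(-180.0, 180.0)),
        world_translation=tuple(rng.uniform(-5.0, 5.0, 3)),
        mount_rotvec=tuple(rng.normal(0.0, 5.0, 3)),
    )


def _cell_config(task: str, environment: str, duration: float,
                 seed: int, error_model: ErrorModel) -> SimulationConfig:
    env = ENVIRONMENTS[environment]
    circ = CircuitConfig(width=env["width"], height=env["height"])
    speed = TASK_SPEEDS[task]
    circ.laps = max(0.5, duration * speed / circ.perimeter)
    return SimulationConfig(circuit=circ, speed=speed, seed=seed, error_model=error_model)


def simulate_pair(config: SimulationConfig, subject: str = "", task: str = "",
                  environment: str = "", gold_kind: str = "ots") -> SimulatedPair:
    """Simulate one full recording cell from a configuration."""
    truth, sync_end = simulate_truth(config)
    gold = subsample_gold(truth, config.rates["device_pose"], config.rates["gold_pose"])
    device = corrupt_to_device(truth, config.error_model, seed=config.seed,
                               device_rate=config.rates["device_pose"])
    pair = SimulatedPair(
        truth=truth, gold=gold, device=device, injected=config.error_model,
        sync_end=sync_end, subject=subject, task=task, environment=environment,
        gold_kind=gold_kind,
    )
    if gold_kind == "wheel":
        speed = horizontal_speed(derive_kinematics(truth))
        pair.wheel = simulate_wheel(
            speed, noise_sd=0.01, rate=config.rates["wheel_imu"],
            seed=config.seed + 1,
        )
        duration = truth.t[-1] - truth.t[0]
        tap_time = 0.5
        pair.device_imu = simulate_tap_imu(
            tap_time, duration, config.rates["device_imu"],
            clock_offset=config.error_model.time_offset, seed=config.seed + 2,
        )
        pair.wheel_imu = simulate_tap_imu(
            tap_time, duration, config.rates["wheel_imu"],
            clock_offset=0.0, seed=config.seed + 3,
        )
    return pair


def generate_study(subjects=3, tasks=("slow_walk", "walk", "run"),
                   environments=("tracking_space", "hallway", "lobby", "courtyard"),
                   duration: float = 60.0, seed: int = 0) -> list:
    """Simulate a full subjects × tasks × environments study.

    Each cell gets a deterministic per-cell seed derived from ``seed``
    and an environment/task-linked default error model, so downstream
    sign patterns (more speed under-estimation in larger environments,
    more drift at higher speeds) are present by construction.
    """
    if isinstance(subjects, int):
        subjects = [f"S{i + 1:02d}" for i in range(subjects)]
    if len(set(subjects)) != len(subjects) or len(set(tasks)) != len(tasks) \
            or len(set(environments)) != len(environments):
        raise ValidationError("duplicate cell labels")
    pairs = []
    for si, subject in enumerate(subjects):
        for ti, task in enumerate(tasks):
            for ei, environment in enumerate(environments):
                ss = np.random.SeedSequence([seed, si, ti, ei])
                cell_seed = int(ss.generate_state(1)[0] % (2 ** 31))
                rng = np.random.default_rng(cell_seed)
                em = default_error_model(task, environment, rng)
                cfg = _cell_config(task, environment, duration, cell_seed, em)
                pairs.append(
                    simulate_pair(cfg, subject, task, environment,
                                  ENVIRONMENTS[environment]["kind"])
                )
    return pairs
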