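"""Surveyor-wheel ("perambulator") gold-standard speed processing.

The wheel carries an axle-mounted gyroscope whose rate, multiplied by
the wheel circumference, gives ground speed, plus a mechanical distance
counter that provides the gold-standard trajectory length directly.

Processing chain: low-pass filter the axle rate (4th-order Butterworth,
10 Hz cutoff, zero-phase by default since the analysis is offline),
convert to speed ``v = C · ω_P`` with ``ω_P`` in revolutions per second,
then clean the series by dropping samples below 0.01 m/s and any
remaining contiguous segment shorter than 3 s (wheel standing still or
being repositioned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import butter, filtfilt, lfilter

from .io_model import ValidationError, WheelRecording
from .kinematics import SpeedSeries

__all__ = [
    "CleanSpeedSeries",
    "filter_wheel_rate",
    "wheel_speed",
    "clean_speed",
    "wheel_trajectory_length",
    "wheel_speed_pipeline",
]


@dataclass
class CleanSpeedSeries:
    """Cleaned wheel speed: retained samples, their segment ids, exclusions."""

    t: np.ndarray
    v: np.ndarray
    segment_ids: np.ndarray
    excluded_count: int
    all_excluded: bool = False

    def __len__(self):
        return len(self.t)


def filter_wheel_rate(omega_p: np.ndarray, fs: float, cutoff_hz: float = 10.0,
                      zero_phase: bool = True) -> np.ndarray:
    """Fourth-order Butterworth low-pass of the axle rate.

    Zero-phase (forward-backward) by default; ``zero_phase=False`` gives
    a single causal pass.
    """
    if fs <= 2.0 * cutoff_hz:
        raise ValidationError(
            f"sampling rate {fs} Hz puts the {cutoff_hz} Hz cutoff at or above Nyquist"
        )
    b, a = butter(4, cutoff_hz / (fs / 2.0), btype="low")
    omega_p = np.asarray(omega_p, dtype=float)
    if zero_phase:
        return filtfilt(b, a, omega_p)
    return lfilter(b, a, omega_p)


def wheel_speed(omega_p_filtered: np.ndarray, circumference: float = 1.0,
                t: np.ndarray | None = None) -> SpeedSeries:
    """Ground speed v = C · ω_P (ω_P in rev/s, C in metres)."""
    if circumference <= 0:
        raise ValidationError("circumference must be positive")
    omega_p_filtered = np.asarray(omega_p_filtered, dtype=float)
    if t is None:
        t = np.arange(len(omega_p_filtered), dtype=float)
    return SpeedSeries(np.asarray(t, dtype=float), circumference * omega_p_filtered)


def clean_speed(series: SpeedSeries, min_speed: float = 0.01,
                min_segment: float = 3.0) -> CleanSpeedSeries:
    """Drop sub-threshold samples and too-short contiguous segments.

    Retained values are passed through unmodified; exclusion counts are
    reported so the behavior is auditable. An all-excluded result is
    returned empty with ``all_excluded=True``.
    """
    t = series.t
    v = series.v
    keep = v >= min_speed
    # label contiguous retained runs
    starts = keep & ~np.concatenate([[False], keep[:-1]])
    seg_id = np.cumsum(starts) - 1
    for sid in range(seg_id[keep].max() + 1 if keep.any() else 0):
        m = keep & (seg_id == sid)
        ts = t[m]
        if ts[-1] - ts[0] < min_segment:
            keep &= ~m
    excluded = int((~keep).sum())
    if not keep.any():
        return CleanSpeedSeries(t[:0], v[:0], np.zeros(0, dtype=int), excluded, True)
    # relabel surviving segments contiguously
    k = keep
    starts = k & ~np.concatenate([[False], k[:-1]])
    ids = (np.cumsum(starts) - 1)[k]
    return CleanSpeedSeries(t[k], v[k], ids.astype(int), excluded)


def wheel_trajectory_length(recording: WheelRecording) -> float:
    """Gold-standard trajectory length straight from the distance counter."""
    if recording.counter_distance is None:
        raise ValidationError("wheel recording has no counter distance")
    if recording.counter_distance < 0:
        raise ValidationError("counter distance cannot be negative")
    return float(recording.counter_distance)


def wheel_speed_pipeline(recording: WheelRecording, cutoff_hz: float = 10.0,
                         min_speed: float = 0.01, min_segment: float = 3.0,
                         zero_phase: bool = True) -> CleanSpeedSeries:
    """Filter → speed → clean, end to end, from a wheel recording."""
    fs = 1.0 / np.median(np.diff(recording.t))
    filt = filter_wheel_rate(recording.omega_p, fs, cutoff_hz, zero_phase)
    speed = wheel_speed(filt, recording.circumference, recording.t)
    return clean_speed(speed, min_speed, min_segment)
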