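"""Raw recordings -> labeled repetitions with derived channels.

Segmentation cuts trough-to-trough windows on a smoothed reference channel
(gyroscope x-axis by default) using prominence-based peak detection, then the
same sample windows are applied to every other channel. Three derived series
are computed per set before slicing: total acceleration, exerted force, and a
complementary-filter yaw estimate.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks, lfilter

from .core import (
    RAW_CHANNELS,
    LabeledRepetition,
    RepetitionWindow,
    SamplingSpec,
    SetRecording,
    SubjectDataset,
    SubjectRecordings,
    ValidationError,
    label_for_rpe,
)

DUMBBELL_MASS_KG = 4.5
RPE_TOLERANCE = 2.0


@dataclass(frozen=True)
class FusionState:
    """Complementary-filter state: current angle plus the two blend weights."""

    angle: float = 0.0
    k_gyro: float = 0.98
    k_acc: float = 0.02

    def __post_init__(self) -> None:
        if not (0.0 <= self.k_gyro <= 1.0 and 0.0 <= self.k_acc <= 1.0):
            raise ValidationError("fusion weights must lie in [0, 1]")
        if abs(self.k_gyro + self.k_acc - 1.0) > 1e-9:
            raise ValidationError("fusion weights must sum to 1")


@dataclass(frozen=True)
class SegmentationConfig:
    """Knobs for trough-to-trough repetition cutting on the reference channel."""

    reference_channel: str = "gx"
    min_period: float = 1.0  # seconds between successive flexion peaks
    prominence_fraction: float = 0.3  # of the set's amplitude range
    smoothing_window: int = 5  # samples, moving average

    def __post_init__(self) -> None:
        if self.min_period <= 0:
            raise ValidationError("min_period must be positive")
        if not 0.0 < self.prominence_fraction < 1.0:
            raise ValidationError("prominence_fraction must lie in (0, 1)")
        if self.smoothing_window < 1:
            raise ValidationError("smoothing_window must be >= 1")


def reconcile_rpe(reported_rpe: float, heart_rate: float, tolerance: float = RPE_TOLERANCE) -> float:
    """Cross-check the reported Borg value against heart rate / 10.

    Consistent reports are kept as-is; inconsistent ones are averaged with the
    heart-rate-derived value and clipped back onto the Borg scale.
    """
    if not 6.0 <= reported_rpe <= 20.0:
        raise ValidationError(f"reported_rpe must be in [6, 20], got {reported_rpe}")
    if heart_rate <= 0:
        raise ValidationError("heart_rate must be positive")
    hr_rpe = heart_rate / 10.0
    if abs(hr_rpe - reported_rpe) <= tolerance:
        return float(reported_rpe)
    return float(np.clip((reported_rpe + hr_rpe) / 2.0, 6.0, 20.0))


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return x.astype(float)
    kernel = np.ones(window) / window
    # edge-pad so the smoothed series keeps the input length
    pad = window // 2
    padded = np.pad(x, (pad, window - 1 - pad), mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def segment_repetitions(recording: SetRecording, config: SegmentationConfig | None = None,
                        sampling: SamplingSpec | None = None) -> list[RepetitionWindow]:
    """Cut one window per detected flexion peak, bounded by adjacent troughs.

    Returns an empty list when no peak clears the prominence threshold
    (e.g. a constant signal).
    """
    config = config or SegmentationConfig()
    if config.reference_channel not in recording.channels:
        raise ValidationError(
            f"reference channel {config.reference_channel!r} absent from recording"
        )
    x = recording.channels[config.reference_channel]
    rate = sampling.rate if sampling is not None else 1.0 / float(
        np.mean(np.diff(recording.timestamps))
    )
    smoothed = _moving_average(x, config.smoothing_window)
    amplitude_range = float(smoothed.max() - smoothed.min())
    if amplitude_range <= 0:
        return []
    distance = max(1, int(round(config.min_period * rate)))
    peaks, _ = find_peaks(
        smoothed, prominence=config.prominence_fraction * amplitude_range, distance=distance
    )
    if len(peaks) == 0:
        return []
    boundaries = [int(np.argmin(smoothed[: peaks[0] + 1]))]
    for left, right in zip(peaks[:-1], peaks[1:]):
        boundaries.append(int(left + 1 + np.argmin(smoothed[left + 1 : right])))
    boundaries.append(int(peaks[-1] + np.argmin(smoothed[peaks[-1] :])))
    windows: list[RepetitionWindow] = []
    for i, peak in enumerate(peaks):
        start, end = boundaries[i], boundaries[i + 1]
        if i == len(peaks) - 1:
            end = end + 1  # include the final trough sample in the last window
        if start < peak < end and end - start >= 3:
            windows.append(RepetitionWindow(start=start, end=end, peak=int(peak)))
    return windows


def propagate_windows(windows: Sequence[RepetitionWindow],
                      channels: dict[str, np.ndarray]) -> list[dict[str, np.ndarray]]:
    """Apply the reference-channel windows, index-identical, to every channel."""
    lengths = {len(v) for v in channels.values()}
    if len(lengths) > 1:
        raise ValidationError(f"channel lengths differ: { {k: len(v) for k, v in channels.items()} }")
    if windows and lengths and max(w.end for w in windows) > max(lengths):
        raise ValidationError("window extends beyond channel length")
    return [{name: series[w.start : w.end] for name, series in channels.items()} for w in windows]


def label_repetitions(windows: Sequence[RepetitionWindow], effective_rpe: float) -> list[str]:
    """One label per window; all repetitions of a set share the set's label."""
    label = label_for_rpe(effective_rpe)
    return [label for _ in windows]


def total_acceleration(ax: np.ndarray, ay: np.ndarray, az: np.ndarray) -> np.ndarray:
    """Pointwise acceleration vector magnitude sqrt(ax^2 + ay^2 + az^2)."""
    ax, ay, az = (np.asarray(a, dtype=float) for a in (ax, ay, az))
    if not len(ax) == len(ay) == len(az):
        raise ValidationError("acceleration channels must share one length")
    return np.sqrt(ax**2 + ay**2 + az**2)


def exerted_force(a_total: np.ndarray, mass: float = DUMBBELL_MASS_KG) -> np.ndarray:
    """F = m * a with the dumbbell mass; no gravity compensation."""
    if mass <= 0:
        raise ValidationError("mass must be positive")
    return mass * np.asarray(a_total, dtype=float)


def acc_angle(ax: np.ndarray, ay: np.ndarray) -> np.ndarray:
    """Accelerometer-derived planar angle atan2(ay, ax), unwrapped, in degrees."""
    return np.degrees(np.unwrap(np.arctan2(np.asarray(ay, float), np.asarray(ax, float))))


def fuse_acc_gyro(gyro_rate: np.ndarray, acc_angle_deg: np.ndarray, dt: float,
                  initial_angle: float = 0.0, state: FusionState | None = None) -> np.ndarray:
    """Complementary filter: angle <- k_g * (angle + gyro * dt) + k_a * acc.

    Applied left-to-right from ``initial_angle``; output length equals input.
    """
    state = state or FusionState(angle=initial_angle)
    gyro_rate = np.asarray(gyro_rate, dtype=float)
    acc_angle_deg = np.asarray(acc_angle_deg, dtype=float)
    if len(gyro_rate) != len(acc_angle_deg):
        raise ValidationError("gyro and accelerometer series must share one length")
    if dt <= 0:
        raise ValidationError("dt must be positive")
    # angle_i = k_g * angle_{i-1} + (k_g * gyro_i * dt + k_a * acc_i)
    drive = state.k_gyro * gyro_rate * dt + state.k_acc * acc_angle_deg
    zi = np.array([state.k_gyro * initial_angle])
    out, _ = lfilter([1.0], [1.0, -state.k_gyro], drive, zi=zi)
    return out


def derive_channels(recording: SetRecording, sampling: SamplingSpec,
                    mass: float = DUMBBELL_MASS_KG, initial_angle: float = 0.0) -> dict[str, np.ndarray]:
    """All nine per-set series: the six raw channels plus the three derived ones."""
    ch = dict(recording.channels)
    a_tot = total_acceleration(ch["ax"], ch["ay"], ch["az"])
    ch["a_total"] = a_tot
    ch["f_exerted"] = exerted_force(a_tot, mass)
    ch["yaw"] = fuse_acc_gyro(ch["gx"], acc_angle(ch["ax"], ch["ay"]), sampling.dt, initial_angle)
    return ch


def process_recording(recording: SetRecording, sampling: SamplingSpec,
                      config: SegmentationConfig | None = None,
                      mass: float = DUMBBELL_MASS_KG,
                      rpe_tolerance: float = RPE_TOLERANCE) -> list[LabeledRepetition]:
    """Segment, derive, and label one set recording. Warm-ups yield no repetitions."""
    if recording.set_index == 0:
        return []
    config = config or SegmentationConfig()
    windows = segment_repetitions(recording, config, sampling)
    if not windows:
        return []
    effective = reconcile_rpe(recording.reported_rpe, recording.heart_rate, rpe_tolerance)
    labels = label_repetitions(windows, effective)
    nine = derive_channels(recording, sampling, mass)
    slices = propagate_windows(windows, nine)
    reps = []
    for window, label, sl in zip(windows, labels, slices):
        reps.append(LabeledRepetition(
            subject_id=recording.subject_id,
            hand=recording.hand,
            set_index=recording.set_index,
            window=window,
            timestamps=recording.timestamps[window.start : window.end],
            channels=sl,
            effective_rpe=effective,
            label=label,
        ))
    return reps


_HAND_ORDER = {"left": 0, "right": 1}


def process_subject(subject: SubjectRecordings, sampling: SamplingSpec,
                    config: SegmentationConfig | None = None,
                    mass: float = DUMBBELL_MASS_KG,
                    rpe_tolerance: float = RPE_TOLERANCE) -> SubjectDataset:
    """Segment every non-warm-up set, preserving (hand, set_index) chronology."""
    reps: list[LabeledRepetition] = []
    ordered = sorted(subject.recordings, key=lambda r: (_HAND_ORDER[r.hand], r.set_index))
    for rec in ordered:
        reps.extend(process_recording(rec, sampling, config, mass, rpe_tolerance))
    return SubjectDataset(subject.subject_id, subject.traits, reps)


def process_cohort(cohort: Sequence[SubjectRecordings], sampling: SamplingSpec,
                   config: SegmentationConfig | None = None,
                   mass: float = DUMBBELL_MASS_KG,
                   rpe_tolerance: float = RPE_TOLERANCE) -> list[SubjectDataset]:
    return [process_subject(s, sampling, config, mass, rpe_tolerance) for s in cohort]
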