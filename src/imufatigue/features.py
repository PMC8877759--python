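"""Eleven per-repetition features on each of the nine channels.

Moment statistics use population (1/N) estimators. RMS is, by convention of
this pipeline, computed on mean-deviations and therefore duplicates the
standard deviation; set ``raw_rms=True`` to get the conventional raw-signal
RMS instead. Skewness and kurtosis are defined as 0 on constant windows.

The two peak-based features (IoP, MSP) use peak indices detected on the
reference channel within each repetition, with per-channel amplitudes read at
those indices.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .core import ALL_CHANNELS, SubjectDataset, ValidationError

FEATURE_NAMES = (
    "min", "max", "mean", "median", "sd", "variance",
    "kurtosis", "rms", "skewness", "iop", "msp",
)
META_COLUMNS = ("subject_id", "hand", "set_index", "label")


def feature_columns(channels: Sequence[str] = ALL_CHANNELS) -> list[str]:
    """Deterministic 99-column header: '<channel>_<feature>' in channel-major order."""
    return [f"{c}_{f}" for c in channels for f in FEATURE_NAMES]


@dataclass(frozen=True)
class PeakSet:
    """Peak times (seconds) and amplitudes (signal units) within one repetition."""

    times: np.ndarray
    amplitudes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))
        if len(self.times) != len(self.amplitudes):
            raise ValidationError("peak times and amplitudes must have equal length")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ValidationError("peak times must be strictly increasing")


def basic_stats(x: Sequence[float], raw_rms: bool = False) -> dict[str, float]:
    """The nine moment/order statistics, population form."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n == 0:
        raise ValidationError("cannot compute statistics of an empty series")
    mean = float(np.mean(x))
    dev = x - mean
    variance = float(np.mean(dev**2))
    sd = float(np.sqrt(variance))
    # sd below float noise at the series' scale counts as constant
    if sd > 1e-12 * max(float(np.max(np.abs(x))), 1e-300):
        z = dev / sd  # standardize first so sd**4 cannot underflow
        skewness = float(np.mean(z**3))
        kurtosis = float(np.mean(z**4))
    else:
        skewness = 0.0
        kurtosis = 0.0
    rms = float(np.sqrt(np.mean(x**2))) if raw_rms else sd
    return {
        "min": float(np.min(x)),
        "max": float(np.max(x)),
        "mean": mean,
        "median": float(np.median(x)),
        "sd": sd,
        "variance": variance,
        "kurtosis": kurtosis,
        "rms": rms,
        "skewness": skewness,
    }


def detect_peaks_in_rep(x: Sequence[float], timestamps: Sequence[float]) -> PeakSet:
    """Local maxima above the repetition mean; falls back to the global maximum.

    Always returns at least one peak, so monotone ramps yield their endpoint.
    """
    x = np.asarray(x, dtype=float)
    t = np.asarray(timestamps, dtype=float)
    if len(x) != len(t):
        raise ValidationError("series and timestamps must share one length")
    if len(x) < 3:
        raise ValidationError("repetition must hold at least 3 samples")
    idx, _ = find_peaks(x, height=float(np.mean(x)))
    if len(idx) == 0:
        idx = np.array([int(np.argmax(x))])
    return PeakSet(times=t[idx], amplitudes=x[idx])


def peak_indices(x: Sequence[float]) -> np.ndarray:
    """Peak sample indices by the same rule as :func:`detect_peaks_in_rep`."""
    x = np.asarray(x, dtype=float)
    idx, _ = find_peaks(x, height=float(np.mean(x)))
    if len(idx) == 0:
        idx = np.array([int(np.argmax(x))])
    return idx


def interval_of_peaks(peaks: PeakSet) -> float:
    """Mean time between successive peaks; 0 with fewer than two peaks."""
    if len(peaks.times) < 2:
        return 0.0
    return float(np.mean(np.diff(peaks.times)))


def mean_slope_peaks(peaks: PeakSet) -> float:
    """Average pairwise amplitude-over-time slope, normalized by N^2.

    Sums (p_j - p_i) / (T_j - T_i) over all ordered pairs i != j (the i = j
    terms are excluded) and divides by N^2; 0 with fewer than two peaks.
    """
    n = len(peaks.times)
    if n < 2:
        return 0.0
    dt = peaks.times[:, None] - peaks.times[None, :]
    if np.any((dt == 0) & ~np.eye(n, dtype=bool)):
        raise ValidationError("duplicate peak times")
    dp = peaks.amplitudes[:, None] - peaks.amplitudes[None, :]
    off = ~np.eye(n, dtype=bool)
    return float(np.sum(dp[off] / dt[off]) / n**2)


def repetition_features(rep_channels: dict[str, np.ndarray], timestamps: np.ndarray,
                        reference_channel: str = "gx", raw_rms: bool = False) -> dict[str, float]:
    """All 99 features of one repetition, keyed '<channel>_<feature>'."""
    missing = [c for c in ALL_CHANNELS if c not in rep_channels]
    if missing:
        raise ValidationError(f"repetition is missing channel(s) {missing}")
    ref_idx = peak_indices(rep_channels[reference_channel])
    t = np.asarray(timestamps, dtype=float)
    out: dict[str, float] = {}
    for channel in ALL_CHANNELS:
        series = np.asarray(rep_channels[channel], dtype=float)
        stats = basic_stats(series, raw_rms=raw_rms)
        peaks = PeakSet(times=t[ref_idx], amplitudes=series[ref_idx])
        stats["iop"] = interval_of_peaks(peaks)
        stats["msp"] = mean_slope_peaks(peaks)
        for name in FEATURE_NAMES:
            out[f"{channel}_{name}"] = stats[name]
    return out


def build_feature_matrix(cohort: Sequence[SubjectDataset], reference_channel: str = "gx",
                         raw_rms: bool = False) -> pd.DataFrame:
    """One row per repetition: 4 metadata columns + 99 feature columns.

    Rows keep the cohort's chronological per-subject ordering.
    """
    columns = list(META_COLUMNS) + feature_columns()
    rows = []
    for subject in cohort:
        for i, rep in enumerate(subject.repetitions):
            try:
                feats = repetition_features(
                    rep.channels, rep.timestamps, reference_channel, raw_rms
                )
            except ValidationError as exc:
                raise ValidationError(
                    f"subject {subject.subject_id} repetition {i}: {exc}"
                ) from exc
            row = {
                "subject_id": subject.subject_id,
                "hand": rep.hand,
                "set_index": rep.set_index,
                "label": rep.label,
            }
            row.update(feats)
            rows.append(row)
    return pd.DataFrame(rows, columns=columns)
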