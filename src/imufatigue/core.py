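"""Shared data model and plain-CSV cohort I/O.

A cohort on disk is one directory per subject::

    root/
      s01/
        traits.csv                # age,height,weight,bmi (one row)
        sets.csv                  # hand,set_index,reported_rpe,heart_rate,file
        left_set0.csv             # timestamp,ax,ay,az,gx,gy,gz
        left_set1.csv
        ...

All numeric fields round-trip bit-exactly (shortest-repr float formatting).
Units are fixed: m/s^2, deg/s, cm, kg; readers never auto-convert.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

HANDS = ("left", "right")
RAW_CHANNELS = ("ax", "ay", "az", "gx", "gy", "gz")
DERIVED_CHANNELS = ("a_total", "f_exerted", "yaw")
ALL_CHANNELS = RAW_CHANNELS + DERIVED_CHANNELS

FATIGUE = "fatigue"
NON_FATIGUE = "non_fatigue"
LABELS = (FATIGUE, NON_FATIGUE)

RPE_MIN = 6.0
RPE_MAX = 20.0
#: strict threshold: a repetition is fatigued iff its effective RPE exceeds this
FATIGUE_RPE_THRESHOLD = 16.0

SIGNAL_COLUMNS = ("timestamp",) + RAW_CHANNELS
TRAITS_COLUMNS = ("age", "height", "weight", "bmi")
SETS_COLUMNS = ("hand", "set_index", "reported_rpe", "heart_rate", "file")


class CohortFormatError(ValueError):
    """A cohort file is structurally malformed (missing column, bad value)."""


class ValidationError(ValueError):
    """A semantic invariant of the data model is violated."""


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index in kg/m^2 from weight in kg and height in cm."""
    if weight <= 0 or height <= 0:
        raise ValidationError(
            f"weight and height must be positive, got weight={weight}, height={height}"
        )
    return weight / (height / 100.0) ** 2


@dataclass(frozen=True)
class PhysicalTraits:
    """Physical trait vector: age (years), height (cm), weight (kg), BMI (kg/m^2)."""

    age: float
    height: float
    weight: float
    bmi: float

    def __post_init__(self) -> None:
        for name in ("age", "height", "weight", "bmi"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be strictly positive")

    @classmethod
    def from_measurements(cls, age: float, height: float, weight: float) -> "PhysicalTraits":
        return cls(age=age, height=height, weight=weight, bmi=compute_bmi(weight, height))

    def as_vector(self) -> np.ndarray:
        return np.array([self.age, self.height, self.weight, self.bmi], dtype=float)


@dataclass(frozen=True)
class SamplingSpec:
    """Sampling rate of the IMU stream; dt is the derived sample period."""

    rate: float = 50.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValidationError("sampling rate must be positive")

    @property
    def dt(self) -> float:
        return 1.0 / self.rate


@dataclass
class SetRecording:
    """One exercise set: six raw IMU channels plus set-level RPE and heart rate.

    set_index 0 is the warm-up; 1..5 are the graded sets.
    """

    subject_id: str
    hand: str
    set_index: int
    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    reported_rpe: float
    heart_rate: float

    def __post_init__(self) -> None:
        if self.hand not in HANDS:
            raise ValidationError(f"hand must be one of {HANDS}, got {self.hand!r}")
        if not 0 <= int(self.set_index) <= 5:
            raise ValidationError(f"set_index must be in 0..5, got {self.set_index}")
        missing = [c for c in RAW_CHANNELS if c not in self.channels]
        if missing:
            raise CohortFormatError(f"recording is missing channel(s) {missing}")
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        self.channels = {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        n = len(self.timestamps)
        if n < 2:
            raise ValidationError("recording must hold at least 2 samples")
        lengths = {k: len(v) for k, v in self.channels.items()}
        if len(set(lengths.values()) | {n}) != 1:
            raise ValidationError(f"channel lengths differ: {lengths}, timestamps={n}")
        if np.any(np.diff(self.timestamps) <= 0):
            bad = int(np.argmax(np.diff(self.timestamps) <= 0))
            raise ValidationError(f"timestamps not strictly increasing at sample {bad + 1}")
        if not RPE_MIN <= self.reported_rpe <= RPE_MAX:
            raise ValidationError(f"reported_rpe must be in [6, 20], got {self.reported_rpe}")

    @property
    def n_samples(self) -> int:
        return len(self.timestamps)


@dataclass(frozen=True)
class RepetitionWindow:
    """Half-open sample window [start, end) with the full-flexion peak inside."""

    start: int
    end: int
    peak: int

    def __post_init__(self) -> None:
        if not self.start < self.peak < self.end:
            raise ValidationError(
                f"window requires start < peak < end, got ({self.start}, {self.peak}, {self.end})"
            )
        if self.end - self.start < 3:
            raise ValidationError("repetition window must span at least 3 samples")

    def __len__(self) -> int:
        return self.end - self.start


def label_for_rpe(effective_rpe: float) -> str:
    """Fatigue iff the effective RPE strictly exceeds 16."""
    if not RPE_MIN <= effective_rpe <= RPE_MAX:
        raise ValidationError(f"effective_rpe must be in [6, 20], got {effective_rpe}")
    return FATIGUE if effective_rpe > FATIGUE_RPE_THRESHOLD else NON_FATIGUE


@dataclass
class LabeledRepetition:
    """A segmented repetition with its nine per-repetition series and fatigue label."""

    subject_id: str
    hand: str
    set_index: int
    window: RepetitionWindow
    timestamps: np.ndarray
    channels: dict[str, np.ndarray]
    effective_rpe: float
    label: str

    def __post_init__(self) -> None:
        if self.label not in LABELS:
            raise ValidationError(f"unknown label {self.label!r}")
        if self.label != label_for_rpe(self.effective_rpe):
            raise ValidationError(
                f"label {self.label!r} inconsistent with effective_rpe {self.effective_rpe}"
            )
        missing = [c for c in ALL_CHANNELS if c not in self.channels]
        if missing:
            raise ValidationError(f"repetition is missing channel(s) {missing}")


@dataclass
class SubjectRecordings:
    """Raw per-subject material before segmentation: traits plus set recordings."""

    subject_id: str
    traits: PhysicalTraits
    recordings: list[SetRecording] = field(default_factory=list)


@dataclass
class SubjectDataset:
    """Segmented, labeled per-subject data, chronological per hand."""

    subject_id: str
    traits: PhysicalTraits
    repetitions: list[LabeledRepetition] = field(default_factory=list)


def _require_columns(df: pd.DataFrame, columns: Sequence[str], path: Path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise CohortFormatError(f"{path}: missing column(s) {missing}")


def _read_signal_file(path: Path) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    df = pd.read_csv(path, float_precision="round_trip")
    _require_columns(df, SIGNAL_COLUMNS, path)
    for col in SIGNAL_COLUMNS:
        values = pd.to_numeric(df[col], errors="coerce")
        if values.isna().any():
            line = int(values.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise CohortFormatError(f"{path}: non-numeric value in column '{col}' at line {line}")
    timestamps = df["timestamp"].to_numpy(dtype=float)
    if np.any(np.diff(timestamps) <= 0):
        line = int(np.argmax(np.diff(timestamps) <= 0)) + 3
        raise ValidationError(f"{path}: timestamps not strictly increasing at line {line}")
    channels = {c: df[c].to_numpy(dtype=float) for c in RAW_CHANNELS}
    return timestamps, channels


def read_cohort(root_path: str | Path, sampling: SamplingSpec | None = None) -> list[SubjectRecordings]:
    """Read every subject directory under ``root_path``.

    ``sampling``, when given, is used only to sanity-check the mean sample
    period (10% jitter tolerance); no resampling is performed.
    """
    root = Path(root_path)
    if not root.is_dir():
        raise FileNotFoundError(f"cohort directory not found: {root}")
    subjects: list[SubjectRecordings] = []
    for subject_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        traits_path = subject_dir / "traits.csv"
        sets_path = subject_dir / "sets.csv"
        if not traits_path.exists() or not sets_path.exists():
            continue  # not a subject directory
        traits_df = pd.read_csv(traits_path, float_precision="round_trip")
        _require_columns(traits_df, TRAITS_COLUMNS, traits_path)
        row = traits_df.iloc[0]
        traits = PhysicalTraits(
            age=float(row["age"]), height=float(row["height"]),
            weight=float(row["weight"]), bmi=float(row["bmi"]),
        )
        sets_df = pd.read_csv(sets_path, float_precision="round_trip")
        _require_columns(sets_df, SETS_COLUMNS, sets_path)
        recordings = []
        for _, srow in sets_df.iterrows():
            sig_path = subject_dir / str(srow["file"])
            if not sig_path.exists():
                raise CohortFormatError(f"{sets_path}: signal file {sig_path.name} not found")
            timestamps, channels = _read_signal_file(sig_path)
            rec = SetRecording(
                subject_id=subject_dir.name,
                hand=str(srow["hand"]),
                set_index=int(srow["set_index"]),
                timestamps=timestamps,
                channels=channels,
                reported_rpe=float(srow["reported_rpe"]),
                heart_rate=float(srow["heart_rate"]),
            )
            if sampling is not None and rec.n_samples > 1:
                mean_dt = float(np.mean(np.diff(rec.timestamps)))
                if not math.isclose(mean_dt, sampling.dt, rel_tol=0.1):
                    raise ValidationError(
                        f"{sig_path}: mean sample period {mean_dt:.4f}s inconsistent "
                        f"with sampling rate {sampling.rate} Hz"
                    )
            recordings.append(rec)
        subjects.append(SubjectRecordings(subject_dir.name, traits, recordings))
    return subjects


def write_cohort(cohort: Sequence[SubjectRecordings], root_path: str | Path) -> list[Path]:
    """Write a cohort to ``root_path``; returns the manifest of written files."""
    root = Path(root_path)
    root.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []
    for subject in cohort:
        sdir = root / subject.subject_id
        sdir.mkdir(parents=True, exist_ok=True)
        traits_path = sdir / "traits.csv"
        t = subject.traits
        pd.DataFrame(
            [{"age": t.age, "height": t.height, "weight": t.weight, "bmi": t.bmi}]
        ).to_csv(traits_path, index=False, float_format="%.17g")
        manifest.append(traits_path)
        set_rows = []
        for rec in subject.recordings:
            fname = f"{rec.hand}_set{rec.set_index}.csv"
            sig_path = sdir / fname
            data = {"timestamp": rec.timestamps}
            data.update({c: rec.channels[c] for c in RAW_CHANNELS})
            pd.DataFrame(data).to_csv(sig_path, index=False, float_format="%.17g")
            manifest.append(sig_path)
            set_rows.append({
                "hand": rec.hand, "set_index": rec.set_index,
                "reported_rpe": rec.reported_rpe, "heart_rate": rec.heart_rate,
                "file": fname,
            })
        sets_path = sdir / "sets.csv"
        pd.DataFrame(set_rows, columns=list(SETS_COLUMNS)).to_csv(sets_path, index=False, float_format="%.17g")
        manifest.append(sets_path)
    return manifest
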