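"""Seeded synthetic cohort generator.

Produces cohorts with the statistical structure the personalization method
assumes: movement-style clusters correlated with physical traits, rising RPE
trajectories that cross the fatigue threshold in the final set, and
fatigue signatures planted directly in the signal family (slower cycles,
smaller amplitudes, growing positive skew in later sets).

The reference-channel waveform is a skew-controllable periodic pulse,
``exp(s * sin(theta))`` rescaled to [-1, 1]: symmetric at s = 0 and
increasingly positively skewed (in the sample-distribution sense) as s grows.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    PhysicalTraits,
    SamplingSpec,
    SetRecording,
    SubjectRecordings,
    ValidationError,
    compute_bmi,
)

DEFAULT_RPE_TRAJECTORY = (9.0, 11.0, 13.0, 15.0, 17.0, 19.0)  # warm-up + 5 sets


@dataclass(frozen=True)
class StyleParams:
    """A subject's movement style and how it degrades with fatigue."""

    base_period: float  # seconds per repetition in the warm-up state
    amplitude: float  # reference-channel amplitude, signal units
    fatigue_period_growth: float  # fractional period growth per set
    fatigue_amplitude_decay: float  # signed fractional amplitude loss per set
    fatigue_skew_gain: float  # waveform skew added per set
    waveform_mix: float = 0.0  # radians; blends quarter-phase-shifted waves

    def __post_init__(self) -> None:
        if self.base_period <= 0 or self.amplitude <= 0:
            raise ValidationError("base_period and amplitude must be positive")
        if self.fatigue_period_growth < 0:
            raise ValidationError("fatigue period growth must be non-negative")
        if not -1.0 < self.fatigue_amplitude_decay < 1.0:
            raise ValidationError("fatigue amplitude decay must lie in (-1, 1)")


@dataclass(frozen=True)
class CohortConfig:
    """Protocol counts, trait ranges, cluster structure, and noise level."""

    n_subjects: int = 25
    sets_per_hand: int = 5
    reps_per_set: int = 15
    warmup_reps: int = 5
    sampling: SamplingSpec = field(default_factory=SamplingSpec)
    age_range: tuple[float, float] = (20.0, 46.0)
    weight_range: tuple[float, float] = (69.0, 127.0)
    height_range: tuple[float, float] = (165.0, 190.0)
    bmi_range: tuple[float, float] = (24.0, 46.0)
    n_style_clusters: int = 3
    trait_style_coupling: float = 1.0
    noise_sd: float = 0.05
    rpe_trajectory: tuple[float, ...] = DEFAULT_RPE_TRAJECTORY
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1 or self.sets_per_hand < 1 or self.reps_per_set < 1:
            raise ValidationError("protocol counts must be positive")
        if not 0.0 <= self.trait_style_coupling <= 1.0:
            raise ValidationError("trait_style_coupling must lie in [0, 1]")
        if len(self.rpe_trajectory) != self.sets_per_hand + 1:
            raise ValidationError("rpe_trajectory must cover warm-up plus every set")
        if any(b < a for a, b in zip(self.rpe_trajectory, self.rpe_trajectory[1:])):
            raise ValidationError("rpe_trajectory must be non-decreasing")
        if self.rpe_trajectory[-1] <= 16.0:
            raise ValidationError("final-set RPE must exceed the fatigue threshold 16")


def _trait_score(traits: PhysicalTraits, config: CohortConfig) -> float:
    """Movement-style position in [0, 1) from the (age, BMI) region.

    The averaged normalized age/BMI score is roughly triangular, so it is
    pushed through the triangular CDF to keep cluster occupancies
    approximately balanced when banded.
    """
    a_lo, a_hi = config.age_range
    b_lo, b_hi = config.bmi_range
    score = 0.5 * (traits.age - a_lo) / (a_hi - a_lo) + 0.5 * (traits.bmi - b_lo) / (b_hi - b_lo)
    score = min(max(score, 0.0), 1.0)
    cdf = 2.0 * score**2 if score <= 0.5 else 1.0 - 2.0 * (1.0 - score) ** 2
    return min(cdf, np.nextafter(1.0, 0.0))


def _style_from_frac(frac: float, rng: np.random.Generator) -> StyleParams:
    # period / amplitude / skew gain all move continuously with the style
    # position, so the fatigue signature reached in late sets overlaps across
    # styles: no single global feature threshold separates the classes, while
    # within a neighborhood of similar styles a simple threshold works
    return StyleParams(
        # period is deliberately unrelated to the style position so that
        # timing cannot serve as a global style identifier
        base_period=max(1.2, 1.8 + rng.normal(0.0, 0.25)),
        amplitude=max(0.4, 1.15 - 0.5 * frac + rng.normal(0.0, 0.02)),
        fatigue_period_growth=max(0.0, 0.06 + rng.normal(0.0, 0.02)),
        # crossing design: low-score styles start high and lose amplitude
        # under fatigue, high-score styles start low and gain it
        # (tremor-like), calibrated so one style's fatigued amplitude matches
        # the other's fresh amplitude. No global amplitude rule separates the
        # classes, while any neighborhood of similar styles shares one
        # monotone direction
        fatigue_amplitude_decay=float(np.clip(0.10 - 0.21 * frac + rng.normal(0.0, 0.01), -0.5, 0.5)),
        fatigue_skew_gain=max(0.01, 0.03 + rng.normal(0.0, 0.01)),
        # the mix is style-neutral on purpose: waveform shape must not
        # identify the style, or a strong global learner reads the style off
        # each repetition and resolves the amplitude crossing without help
        waveform_mix=float(np.clip(np.pi / 8.0 + rng.normal(0.0, 0.05), 0.0, np.pi / 2.0)),
    )


def sample_subject(config: CohortConfig,
                   rng: np.random.Generator) -> tuple[PhysicalTraits, StyleParams, int]:
    """Draw traits (uniform, BMI by rejection into range), a style position
    coupled to the (age, BMI) region at strength ``trait_style_coupling``,
    and the style itself. The cluster id is the banded style position."""
    for _ in range(10_000):
        age = float(rng.integers(int(config.age_range[0]), int(config.age_range[1]) + 1))
        height = float(rng.uniform(*config.height_range))
        weight = float(rng.uniform(*config.weight_range))
        bmi = compute_bmi(weight, height)
        if config.bmi_range[0] <= bmi <= config.bmi_range[1]:
            break
    else:
        raise ValidationError("trait ranges admit no BMI in the configured range")
    traits = PhysicalTraits(age=age, height=height, weight=weight, bmi=bmi)
    if rng.uniform() < config.trait_style_coupling:
        frac = _trait_score(traits, config)
    else:
        frac = float(rng.uniform())
    cluster = min(int(frac * config.n_style_clusters), config.n_style_clusters - 1)
    return traits, _style_from_frac(frac, rng), cluster


def _skewed_wave(theta: np.ndarray, skew: float) -> np.ndarray:
    """exp(skew * sin(theta)) rescaled to [-1, 1]; plain sine at skew = 0."""
    if abs(skew) < 1e-9:
        return np.sin(theta)
    w = np.exp(skew * np.sin(theta))
    w_max, w_min = np.exp(skew), np.exp(-skew)
    return (w - (w_max + w_min) / 2.0) / ((w_max - w_min) / 2.0)


def generate_set_signal(subject_id: str, hand: str, style: StyleParams, set_index: int,
                        config: CohortConfig, rng: np.random.Generator) -> SetRecording:
    """One set's six-channel recording with the fatigue signatures applied.

    Set ``set_index`` runs at period * (1 + growth)^set_index and amplitude *
    (1 - decay)^set_index, with waveform skew growing per set; the remaining
    channels are phase-shifted, attenuated copies of the reference plus noise.
    """
    if not 0 <= set_index <= config.sets_per_hand:
        raise ValidationError(f"set_index must be in 0..{config.sets_per_hand}")
    n_reps = config.warmup_reps if set_index == 0 else config.reps_per_set
    # the RPE jitter and the signal degradation share one severity draw, so
    # the reported exertion co-varies with what the signal actually shows
    jitter = int(rng.integers(-1, 2))
    severity = max(0.0, set_index + 0.5 * jitter) if set_index > 0 else 0.0
    # multiplicative per-set timing noise keeps single-set pace readings from
    # revealing severity; the growth trend survives only on average
    period = (style.base_period * (1.0 + style.fatigue_period_growth) ** severity
              * float(np.exp(rng.normal(0.0, 0.08))))
    amplitude = style.amplitude * (1.0 - style.fatigue_amplitude_decay) ** severity
    skew = style.fatigue_skew_gain * severity
    rate = config.sampling.rate
    n = int(round(n_reps * period * rate))
    t = np.arange(n) / rate
    theta = -np.pi / 2.0 + 2.0 * np.pi * t / period  # trough-to-trough cycles

    mix_a, mix_b = np.cos(style.waveform_mix), np.sin(style.waveform_mix)

    def chan(scale: float, phase: float, offset: float = 0.0) -> np.ndarray:
        shape = (mix_a * _skewed_wave(theta + phase, skew)
                 + mix_b * _skewed_wave(theta + phase + np.pi / 2.0, skew))
        return offset + scale * amplitude * shape + rng.normal(0.0, config.noise_sd, n)

    channels = {
        "gx": chan(1.0, 0.0),
        "gy": chan(0.6, -np.pi / 3.0),
        "gz": chan(0.35, np.pi / 3.0),
        "ax": chan(0.45, np.pi / 6.0),
        "ay": chan(0.55, -np.pi / 4.0),
        "az": chan(-0.35, 0.0, offset=9.81),
    }
    rpe = float(np.clip(config.rpe_trajectory[set_index] + jitter, 6, 20))
    heart_rate = float(10.0 * rpe + rng.normal(0.0, 5.0))
    return SetRecording(
        subject_id=subject_id, hand=hand, set_index=set_index,
        timestamps=t, channels=channels, reported_rpe=rpe, heart_rate=heart_rate,
    )


def generate_session(subject_id: str, hand: str, style: StyleParams, config: CohortConfig,
                     rng: np.random.Generator) -> list[SetRecording]:
    """One hand's full session: warm-up plus every graded set (6 RPE reports)."""
    return [
        generate_set_signal(subject_id, hand, style, set_index, config, rng)
        for set_index in range(config.sets_per_hand + 1)
    ]


def generate_cohort(config: CohortConfig | None = None
                    ) -> tuple[list[SubjectRecordings], pd.DataFrame]:
    """The full cohort plus its ground-truth manifest (cluster and style per
    subject). Deterministic in ``config.seed``; both hands share one style but
    carry independent noise."""
    config = config or CohortConfig()
    rng = np.random.default_rng(config.seed)
    cohort: list[SubjectRecordings] = []
    manifest_rows = []
    width = max(2, len(str(config.n_subjects)))
    for i in range(config.n_subjects):
        subject_id = f"s{i + 1:0{width}d}"
        traits, style, cluster = sample_subject(config, rng)
        recordings: list[SetRecording] = []
        for hand in ("left", "right"):
            recordings.extend(generate_session(subject_id, hand, style, config, rng))
        cohort.append(SubjectRecordings(subject_id, traits, recordings))
        manifest_rows.append({
            "subject_id": subject_id, "cluster": cluster,
            "age": traits.age, "height": traits.height,
            "weight": traits.weight, "bmi": traits.bmi,
            "base_period": style.base_period, "amplitude": style.amplitude,
            "fatigue_period_growth": style.fatigue_period_growth,
            "fatigue_amplitude_decay": style.fatigue_amplitude_decay,
            "fatigue_skew_gain": style.fatigue_skew_gain,
        })
    return cohort, pd.DataFrame(manifest_rows)


def expected_repetition_count(config: CohortConfig | None = None) -> int:
    """Protocol arithmetic: subjects x sets x reps x 2 hands, warm-ups excluded."""
    config = config or CohortConfig()
    return config.n_subjects * config.sets_per_hand * config.reps_per_set * 2
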