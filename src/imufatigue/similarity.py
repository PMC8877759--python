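"""Physical/signal/total similarity between a test subject and a crowd.

Distances are Manhattan sums over min-max-normalized vectors; similarity is
exp(-gamma * distance); total similarity is the alpha/beta convex blend of the
physical and signal similarities.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import PhysicalTraits, ValidationError

DEFAULT_ALPHA = 0.4
DEFAULT_BETA = 0.6
DEFAULT_GAMMA = 14.0

#: the eleven per-repetition features entering the signal distance
SIGNAL_FEATURE_DIM = 11


@dataclass(frozen=True)
class SimilarityParams:
    """Blend weights alpha/beta (alpha + beta = 1) and exponential scale gamma.

    The degenerate pair alpha = beta = 0 is accepted as the cross-subject
    sentinel: every total similarity becomes 0 and downstream weighting falls
    back to uniform, mimicking a standard cross-subject model.
    """

    alpha: float = DEFAULT_ALPHA
    beta: float = DEFAULT_BETA
    gamma: float = DEFAULT_GAMMA

    def __post_init__(self) -> None:
        if not (0.0 <= self.alpha <= 1.0 and 0.0 <= self.beta <= 1.0):
            raise ValidationError("alpha and beta must lie in [0, 1]")
        if self.gamma < 0:
            raise ValidationError("gamma must be non-negative")
        is_cross = self.alpha == 0.0 and self.beta == 0.0
        if not is_cross and abs(self.alpha + self.beta - 1.0) > 1e-9:
            raise ValidationError(
                f"alpha + beta must equal 1 (or both be 0), got {self.alpha} + {self.beta}"
            )

    @property
    def is_cross_subject(self) -> bool:
        return self.alpha == 0.0 and self.beta == 0.0

    @classmethod
    def cross_subject(cls, gamma: float = DEFAULT_GAMMA) -> "SimilarityParams":
        return cls(alpha=0.0, beta=0.0, gamma=gamma)


class MinMaxNormalizer:
    """Per-dimension min-max scaler fitted on training rows only.

    Query values outside the training range are clipped into [0, 1]; constant
    dimensions map to 0.
    """

    def __init__(self, mins: np.ndarray, maxs: np.ndarray):
        self.mins = np.asarray(mins, dtype=float)
        self.maxs = np.asarray(maxs, dtype=float)
        if np.any(self.maxs < self.mins):
            raise ValidationError("max < min in normalization stats")

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        span = self.maxs - self.mins
        safe = np.where(span > 0, span, 1.0)
        scaled = (x - self.mins) / safe
        scaled = np.where(span > 0, scaled, 0.0)
        return np.clip(scaled, 0.0, 1.0)


def fit_minmax(vectors: np.ndarray) -> MinMaxNormalizer:
    """Fit per-dimension min/max on training rows (n, d)."""
    vectors = np.atleast_2d(np.asarray(vectors, dtype=float))
    if vectors.size == 0:
        raise ValidationError("cannot fit normalization on an empty training set")
    return MinMaxNormalizer(vectors.min(axis=0), vectors.max(axis=0))


def physical_distance(vq: np.ndarray, vp: np.ndarray) -> float:
    """Manhattan distance over the four normalized physical traits."""
    vq = np.asarray(vq, dtype=float)
    vp = np.asarray(vp, dtype=float)
    if vq.shape != (4,) or vp.shape != (4,):
        raise ValidationError(f"trait vectors must have length 4, got {vq.shape} and {vp.shape}")
    return float(np.sum(np.abs(vq - vp)))


def signal_distance(fq: np.ndarray, fp: np.ndarray) -> float:
    """Manhattan distance over 11 features x L repetitions.

    Repetitions are aligned chronologically; L is the smaller of the two
    repetition counts, so extra rows on the longer side are ignored.
    """
    fq = np.atleast_2d(np.asarray(fq, dtype=float))
    fp = np.atleast_2d(np.asarray(fp, dtype=float))
    if fq.shape[0] == 0 or fp.shape[0] == 0:
        raise ValidationError("both subjects must provide at least one repetition")
    if fq.shape[1] != SIGNAL_FEATURE_DIM or fp.shape[1] != SIGNAL_FEATURE_DIM:
        raise ValidationError(
            f"feature blocks must have {SIGNAL_FEATURE_DIM} columns, "
            f"got {fq.shape[1]} and {fp.shape[1]}"
        )
    length = min(fq.shape[0], fp.shape[0])
    return float(np.sum(np.abs(fq[:length] - fp[:length])))


def similarity_from_distance(d: float, gamma: float) -> float:
    """exp(-gamma * d); 1 at d = 0 or gamma = 0, decaying in both arguments."""
    if d < 0 or gamma < 0:
        raise ValidationError("distance and gamma must be non-negative")
    return math.exp(-gamma * d)


def total_similarity(sim_phy: float, sim_sig: float, params: SimilarityParams) -> float:
    """alpha * sim_phy + beta * sim_sig."""
    if not (0.0 <= sim_phy <= 1.0 and 0.0 <= sim_sig <= 1.0):
        raise ValidationError("similarities must lie in [0, 1]")
    return params.alpha * sim_phy + params.beta * sim_sig


@dataclass(frozen=True)
class SimilarityScore:
    """All pairwise scores between the test subject and one crowd member."""

    other_subject: str
    d_phy: float
    d_sig: float
    sim_phy: float
    sim_sig: float
    sim_total: float


@dataclass(frozen=True)
class CrowdMember:
    """One crowd subject's inputs to the ranking: id, traits, signal sample."""

    subject_id: str
    traits: PhysicalTraits
    signal_features: np.ndarray  # (L, 11), chronological


def rank_crowd(test_id: str, test_traits: PhysicalTraits, test_signal_features: np.ndarray,
               crowd: Sequence[CrowdMember], params: SimilarityParams,
               normalize_signal: bool = True,
               scale_signal_distance_by_reps: bool = True) -> list[SimilarityScore]:
    """Score the test subject against every crowd member, best first.

    Normalization statistics come from the crowd only; ties in total
    similarity break lexicographically by subject id.

    ``scale_signal_distance_by_reps`` divides the signal distance by the
    number of aligned repetitions before exponentiation, keeping d_sig on a
    scale comparable to d_phy so one gamma can serve both (with the raw sum,
    exp(-gamma * d_sig) underflows for every pair and the signal term of the
    blend goes dead). Disable it for the distance exactly as summed.
    """
    if not crowd:
        raise ValidationError("crowd must be non-empty")
    if any(m.subject_id == test_id for m in crowd):
        raise ValidationError(f"test subject {test_id!r} must not appear in the crowd")

    trait_norm = fit_minmax(np.stack([m.traits.as_vector() for m in crowd]))
    vq = trait_norm.transform(test_traits.as_vector())

    fq = np.atleast_2d(np.asarray(test_signal_features, dtype=float))
    if normalize_signal:
        pooled = np.vstack([np.atleast_2d(m.signal_features) for m in crowd])
        sig_norm = fit_minmax(pooled)
        fq = sig_norm.transform(fq)

    scores = []
    for member in crowd:
        vp = trait_norm.transform(member.traits.as_vector())
        fp = np.atleast_2d(np.asarray(member.signal_features, dtype=float))
        if normalize_signal:
            fp = sig_norm.transform(fp)
        d_phy = physical_distance(vq, vp)
        d_sig = signal_distance(fq, fp)
        if scale_signal_distance_by_reps:
            d_sig /= min(fq.shape[0], fp.shape[0])
        sim_phy = similarity_from_distance(d_phy, params.gamma)
        sim_sig = similarity_from_distance(d_sig, params.gamma)
        scores.append(SimilarityScore(
            other_subject=member.subject_id,
            d_phy=d_phy, d_sig=d_sig,
            sim_phy=sim_phy, sim_sig=sim_sig,
            sim_total=total_similarity(sim_phy, sim_sig, params),
        ))
    return sorted(scores, key=lambda s: (-s.sim_total, s.other_subject))
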