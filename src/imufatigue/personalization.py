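"""Similarity-weighted training sets and boosted classifiers.

Crowd rows are weighted proportionally to their subject's total similarity
(divided by the subject's row count, so a subject's mass does not grow with
how much data they contributed). Training uses discrete two-class boosting:
decision trees consume the maintained weight distribution natively, the
neural net through weighted resampling.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .core import ValidationError
from .similarity import SimilarityScore

logger = logging.getLogger(__name__)

DEFAULT_BUDGET_BASIS = 75  # repetitions per hand: 5 sets x 15
MAX_BUDGET_FRACTION = 0.6


@dataclass(frozen=True)
class ModelConfig:
    """Base learner and boosting hyper-parameters (declared defaults, not tuned)."""

    base_learner: str = "decision_tree"  # or "neural_net"
    n_rounds: int = 50
    learning_rate: float = 1.0
    tree_max_depth: int = 3
    ann_hidden_units: int = 16
    ann_epochs: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_learner not in ("decision_tree", "neural_net"):
            raise ValidationError(f"unknown base learner {self.base_learner!r}")
        if self.n_rounds < 1:
            raise ValidationError("n_rounds must be >= 1")

    @classmethod
    def tree(cls, **kwargs) -> "ModelConfig":
        return cls(base_learner="decision_tree", **kwargs)

    @classmethod
    def ann(cls, **kwargs) -> "ModelConfig":
        kwargs.setdefault("n_rounds", 10)
        return cls(base_learner="neural_net", **kwargs)

    def with_seed(self, seed: int) -> "ModelConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class BudgetSpec:
    """How much of the test subject's own data may join training."""

    fraction: float = 0.0
    reps_per_hand_basis: int = DEFAULT_BUDGET_BASIS

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= MAX_BUDGET_FRACTION + 1e-12:
            raise ValidationError(
                f"budget fraction must lie in [0, {MAX_BUDGET_FRACTION}], got {self.fraction}"
            )
        if self.reps_per_hand_basis <= 0:
            raise ValidationError("reps_per_hand_basis must be positive")


@dataclass
class WeightedTrainingSet:
    """Feature rows, labels, normalized sample weights, and row provenance."""

    X: np.ndarray
    y: np.ndarray
    sample_weights: np.ndarray
    subject_ids: np.ndarray
    source: np.ndarray  # "crowd" or "test_subject" per row

    def __post_init__(self) -> None:
        n = len(self.y)
        if not len(self.X) == len(self.sample_weights) == len(self.subject_ids) == len(self.source) == n:
            raise ValidationError("training-set fields must share one length")
        if np.any(self.sample_weights < 0):
            raise ValidationError("sample weights must be non-negative")
        total = float(self.sample_weights.sum())
        if n and abs(total - 1.0) > 1e-9:
            raise ValidationError(f"sample weights must sum to 1, got {total}")


def weights_from_similarity(scores: Sequence[SimilarityScore],
                            row_subject_ids: Sequence[str]) -> np.ndarray:
    """Per-row weights proportional to sim_total(subject) / n_rows(subject).

    Rows of the same subject share one weight; the result sums to 1. When
    every similarity is zero the weights fall back to uniform.
    """
    row_subject_ids = np.asarray(row_subject_ids)
    sims = {s.other_subject: s.sim_total for s in scores}
    ids, counts = np.unique(row_subject_ids, return_counts=True)
    missing = [i for i in ids if i not in sims]
    if missing:
        raise ValidationError(f"no similarity score for subject(s) {missing}")
    n_rows = dict(zip(ids, counts))
    per_row = np.array([sims[i] / n_rows[i] for i in row_subject_ids], dtype=float)
    total = per_row.sum()
    if total <= 0:
        logger.warning("all similarities are zero; falling back to uniform weights")
        return np.full(len(row_subject_ids), 1.0 / len(row_subject_ids))
    return per_row / total


def select_validation_split(scores: Sequence[SimilarityScore]) -> tuple[list[str], str]:
    """Highest-similarity subject becomes the validation hold-out; rest train.

    Ties at the top break lexicographically by subject id.
    """
    if len(scores) < 2:
        raise ValidationError("need at least 2 crowd subjects to split")
    ranked = sorted(scores, key=lambda s: (-s.sim_total, s.other_subject))
    validation = ranked[0].other_subject
    train = [s.other_subject for s in ranked[1:]]
    return train, validation


def budget_to_repetitions(fraction: float, basis: int = DEFAULT_BUDGET_BASIS) -> int:
    """Round-half-up(fraction * basis); e.g. 10% of 75 -> 8, 20% -> 15."""
    spec = BudgetSpec(fraction=fraction, reps_per_hand_basis=basis)  # validates
    return int(np.floor(spec.fraction * spec.reps_per_hand_basis + 0.5))


def mix_budget(crowd_X: np.ndarray, crowd_y: np.ndarray, crowd_weights: np.ndarray,
               crowd_ids: Sequence[str], test_X: np.ndarray, test_y: np.ndarray,
               test_id: str, fraction: float,
               basis: int = DEFAULT_BUDGET_BASIS) -> tuple[WeightedTrainingSet, np.ndarray, np.ndarray]:
    """Blend the first ``fraction * basis`` test-subject rows into training.

    Budget rows are chronological and enter with the uniform-per-row mass they
    would hold in the combined set; the crowd keeps the remaining mass split
    by its similarity weights. Returns the training set plus the held-out
    test rows (X, y) - the remainder of the test subject's data.
    """
    crowd_X = np.asarray(crowd_X, dtype=float)
    test_X = np.asarray(test_X, dtype=float)
    n_budget = budget_to_repetitions(fraction, basis)
    if n_budget > len(test_X):
        raise ValidationError(
            f"budget of {n_budget} rows exceeds the {len(test_X)} available test-subject rows"
        )
    budget_X, held_X = test_X[:n_budget], test_X[n_budget:]
    budget_y, held_y = np.asarray(test_y)[:n_budget], np.asarray(test_y)[n_budget:]
    n_c, n_b = len(crowd_X), n_budget
    n_total = n_c + n_b
    crowd_w = np.asarray(crowd_weights, dtype=float)
    if abs(crowd_w.sum() - 1.0) > 1e-9:
        raise ValidationError("crowd weights must sum to 1")
    budget_mass = n_b / n_total
    weights = np.concatenate([crowd_w * (1.0 - budget_mass),
                              np.full(n_b, budget_mass / n_b if n_b else 0.0)])
    ts = WeightedTrainingSet(
        X=np.vstack([crowd_X, budget_X]) if n_b else crowd_X.copy(),
        y=np.concatenate([crowd_y, budget_y]),
        sample_weights=weights,
        subject_ids=np.concatenate([np.asarray(crowd_ids), np.full(n_b, test_id)]),
        source=np.concatenate([np.full(n_c, "crowd"), np.full(n_b, "test_subject")]),
    )
    return ts, held_X, held_y


class SingleClassError(ValidationError):
    """Training data contains only one of the two labels."""


class BoostedClassifier:
    """Discrete two-class boosting seeded from an arbitrary weight distribution.

    Trees receive the maintained distribution as native sample weights; the
    neural net is fitted on a weighted bootstrap resample each round. With one
    round and uniform weights the tree variant reduces to a single weighted
    tree. Deterministic given ``config.seed``.
    """

    def __init__(self, config: ModelConfig):
        self.config = config
        self.estimators_: list = []
        self.alphas_: list[float] = []
        self.classes_: np.ndarray | None = None

    def _make_base(self, round_index: int):
        seed = self.config.seed * 1000 + round_index
        if self.config.base_learner == "decision_tree":
            return DecisionTreeClassifier(max_depth=self.config.tree_max_depth, random_state=seed)
        # the net is scale-sensitive; standardize features inside the learner
        return make_pipeline(
            StandardScaler(),
            MLPClassifier(
                hidden_layer_sizes=(self.config.ann_hidden_units,),
                max_iter=self.config.ann_epochs,
                random_state=seed,
            ),
        )

    def fit(self, X: np.ndarray, y: Sequence, sample_weight: np.ndarray | None = None) -> "BoostedClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise SingleClassError(
                f"training data holds only class {classes[0]!r}; both classes are required"
            )
        if len(classes) > 2:
            raise ValidationError("only two-class problems are supported")
        self.classes_ = classes
        n = len(y)
        if sample_weight is None:
            w = np.full(n, 1.0 / n)
        else:
            w = np.asarray(sample_weight, dtype=float)
            if len(w) != n or np.any(w < 0) or w.sum() <= 0:
                raise ValidationError("invalid sample weights")
            w = w / w.sum()
        rng = np.random.default_rng(self.config.seed)
        self.estimators_, self.alphas_ = [], []
        eps = np.finfo(float).eps
        for m in range(self.config.n_rounds):
            est = self._make_base(m)
            if self.config.base_learner == "decision_tree":
                est.fit(X, y, sample_weight=w * n)
            else:
                idx = rng.choice(n, size=n, replace=True, p=w)
                if len(np.unique(y[idx])) < 2:  # degenerate resample; force both classes in
                    idx[0] = int(np.argmax(y == classes[0]))
                    idx[1] = int(np.argmax(y == classes[1]))
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    est.fit(X[idx], y[idx])
            pred = est.predict(X)
            miss = pred != y
            err = float(w[miss].sum())
            if err <= eps:
                self.estimators_.append(est)
                self.alphas_.append(self.config.learning_rate * 0.5 * np.log(1.0 / eps))
                break
            if err >= 0.5:
                if not self.estimators_:  # keep a usable (if weak) model
                    self.estimators_.append(est)
                    self.alphas_.append(eps)
                break
            alpha = self.config.learning_rate * 0.5 * float(np.log((1.0 - err) / err))
            self.estimators_.append(est)
            self.alphas_.append(alpha)
            w = w * np.exp(np.where(miss, alpha, -alpha))
            w = w / w.sum()
        return self

    def decision_scores(self, X: np.ndarray) -> np.ndarray:
        """Signed margin: positive favors classes_[1]."""
        if self.classes_ is None:
            raise ValidationError("classifier is not fitted")
        X = np.asarray(X, dtype=float)
        score = np.zeros(len(X))
        for est, alpha in zip(self.estimators_, self.alphas_):
            score += alpha * np.where(est.predict(X) == self.classes_[1], 1.0, -1.0)
        return score

    def predict(self, X: np.ndarray) -> np.ndarray:
        score = self.decision_scores(X)
        return np.where(score > 0, self.classes_[1], self.classes_[0])


def train_personalized(ts: WeightedTrainingSet, config: ModelConfig) -> BoostedClassifier:
    """Boosting initialized from the similarity-derived sample weights."""
    return BoostedClassifier(config).fit(ts.X, ts.y, sample_weight=ts.sample_weights)


def train_cross_subject(X: np.ndarray, y: Sequence, config: ModelConfig) -> BoostedClassifier:
    """Plain cross-subject boosting: uniform initial weights."""
    return BoostedClassifier(config).fit(X, y)


def train_subject_specific(test_X: np.ndarray, test_y: Sequence, fraction: float,
                           config: ModelConfig,
                           basis: int = DEFAULT_BUDGET_BASIS) -> tuple[BoostedClassifier, np.ndarray, np.ndarray]:
    """Train on the test subject's first ``fraction * basis`` rows only.

    Returns the model plus the held-out remainder (X, y). fraction must be
    positive: there is no subject-specific model without subject data.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError("subject-specific fraction must lie in (0, 1]")
    test_X = np.asarray(test_X, dtype=float)
    test_y = np.asarray(test_y)
    n = int(np.floor(fraction * basis + 0.5))
    n = min(n, len(test_X))
    if n < 1:
        raise ValidationError("subject-specific budget selects no rows")
    model = BoostedClassifier(config).fit(test_X[:n], test_y[:n])
    return model, test_X[n:], test_y[n:]
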