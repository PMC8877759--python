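"""Confusion-matrix metrics, LOOCV, parameter sweeps, and budget curves.

Metrics are kept as fractions internally; report writers multiply by 100.
Aggregates over leave-one-subject-out folds are per-fold means with a
normal-approximation 95% confidence interval (mean +/- 1.96 * SE).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import FATIGUE, PhysicalTraits, SubjectDataset, ValidationError
from .features import FEATURE_NAMES, build_feature_matrix, feature_columns
from .personalization import (
    ModelConfig,
    SingleClassError,
    budget_to_repetitions,
    mix_budget,
    select_validation_split,
    train_personalized,
    train_subject_specific,
    weights_from_similarity,
)
from .similarity import CrowdMember, SimilarityParams, rank_crowd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Table-style fatigue confusion counts."""

    tp: int  # true fatigue
    fp: int  # false fatigue
    fn: int  # false non-fatigue
    tn: int  # true non-fatigue

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(y_true: Sequence, y_pred: Sequence, positive: str = FATIGUE) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if len(y_true) != len(y_pred) or len(y_true) == 0:
        raise ValidationError("y_true and y_pred must have equal, non-zero length")
    pos_t = y_true == positive
    pos_p = y_pred == positive
    return ConfusionCounts(
        tp=int(np.sum(pos_t & pos_p)),
        fp=int(np.sum(~pos_t & pos_p)),
        fn=int(np.sum(pos_t & ~pos_p)),
        tn=int(np.sum(~pos_t & ~pos_p)),
    )


@dataclass(frozen=True)
class MetricsReport:
    """Accuracy, precision, recall, F1 as fractions in [0, 1]."""

    accuracy: float
    precision: float
    recall: float
    f1: float


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0. Scale-agnostic."""
    if precision < 0 or recall < 0:
        raise ValidationError("precision and recall must be non-negative")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def metrics(c: ConfusionCounts) -> MetricsReport:
    if c.total < 1:
        raise ValidationError("empty confusion matrix")
    accuracy = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return MetricsReport(accuracy, precision, recall, f1_from_precision_recall(precision, recall))


def accuracy_gain_ratio(delta_accuracy: float, n_reps: int) -> float:
    """Accuracy change (percentage points) per test-subject repetition."""
    if n_reps < 1:
        raise ValidationError("n_reps must be >= 1")
    return delta_accuracy / n_reps


def comparison_table(accuracies: Mapping[str, float],
                     test_ids: Mapping[str, Sequence] | None = None) -> pd.DataFrame:
    """Pairwise accuracy deltas, row minus column, on the given scale.

    When ``test_ids`` is provided every model must have been evaluated on the
    identical held-out rows.
    """
    names = list(accuracies)
    if test_ids is not None:
        ref = list(test_ids[names[0]])
        for name in names[1:]:
            if list(test_ids[name]) != ref:
                raise ValidationError(f"model {name!r} was evaluated on a different test set")
    table = pd.DataFrame(index=names, columns=names, dtype=float)
    for a in names:
        for b in names:
            table.loc[a, b] = accuracies[a] - accuracies[b]
    return table


# ---------------------------------------------------------------------------
# pipeline plumbing on top of the feature table


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a fold needs: similarity params, model, sampling of the
    similarity block, and the test-subject budget basis."""

    params: SimilarityParams = field(default_factory=SimilarityParams)
    model: ModelConfig = field(default_factory=ModelConfig)
    sample_reps: int = 15
    signal_channel: str = "gx"
    normalize_signal: bool = True
    use_validation_holdout: bool = True
    budget_basis: int = 75

    def with_params(self, params: SimilarityParams) -> "PipelineConfig":
        return replace(self, params=params)


@dataclass
class FoldResult:
    subject_id: str
    report: MetricsReport | None
    counts: ConfusionCounts | None
    n_test: int
    skipped: bool = False
    reason: str = ""
    model: object | None = None


@dataclass
class LoocvResult:
    folds: list[FoldResult]
    mean: MetricsReport
    ci95: MetricsReport
    n_skipped: int


def prepare_tables(cohort: Sequence[SubjectDataset]) -> tuple[pd.DataFrame, dict[str, PhysicalTraits]]:
    """Feature table plus the traits lookup the drivers consume."""
    return build_feature_matrix(cohort), {s.subject_id: s.traits for s in cohort}


def _signal_feature_block(sub_df: pd.DataFrame, channel: str, sample_reps: int) -> np.ndarray:
    cols = [f"{channel}_{f}" for f in FEATURE_NAMES]
    return sub_df[cols].to_numpy(dtype=float)[:sample_reps]


def _xy(df: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    return df[feature_columns()].to_numpy(dtype=float), df["label"].to_numpy()


def run_fold(features: pd.DataFrame, traits: Mapping[str, PhysicalTraits], test_subject: str,
             cfg: PipelineConfig, mode: str = "personalized", fraction: float = 0.0) -> FoldResult:
    """Train one model family with ``test_subject`` held out and evaluate it.

    Modes: ``cross`` (uniform weights over the crowd), ``personalized``
    (similarity weights plus optional budget rows), ``specific`` (test-subject
    rows only). Budget/held-out rows are chronological and disjoint.
    """
    if mode not in ("cross", "personalized", "specific"):
        raise ValidationError(f"unknown mode {mode!r}")
    test_df = features[features["subject_id"] == test_subject]
    if test_df.empty:
        raise ValidationError(f"no rows for test subject {test_subject!r}")
    test_X, test_y = _xy(test_df)
    crowd_df = features[features["subject_id"] != test_subject]
    try:
        if mode == "specific":
            if fraction == 0.0:
                return FoldResult(test_subject, None, None, 0, skipped=True,
                                  reason="subject-specific model undefined at fraction 0")
            model, held_X, held_y = train_subject_specific(
                test_X, test_y, fraction, cfg.model, basis=cfg.budget_basis)
        else:
            if mode == "cross":
                # the cross-subject model is the same pipeline with the
                # alpha = beta = 0 sentinel: all similarities collapse to 0,
                # weighting falls back to uniform, and the validation
                # hold-out degenerates to the deterministic tie-break
                cfg = cfg.with_params(SimilarityParams.cross_subject(cfg.params.gamma))
            crowd_ids = sorted(crowd_df["subject_id"].unique())
            members = [
                CrowdMember(
                    subject_id=cid,
                    traits=traits[cid],
                    signal_features=_signal_feature_block(
                        crowd_df[crowd_df["subject_id"] == cid], cfg.signal_channel, cfg.sample_reps),
                )
                for cid in crowd_ids
            ]
            scores = rank_crowd(
                test_subject, traits[test_subject],
                _signal_feature_block(test_df, cfg.signal_channel, cfg.sample_reps),
                members, cfg.params, normalize_signal=cfg.normalize_signal,
            )
            if cfg.use_validation_holdout and len(scores) >= 2:
                train_ids, _validation_id = select_validation_split(scores)
            else:
                train_ids = [s.other_subject for s in scores]
            train_df = crowd_df[crowd_df["subject_id"].isin(train_ids)]
            crowd_X, crowd_y = _xy(train_df)
            row_ids = train_df["subject_id"].to_numpy()
            if cfg.params.is_cross_subject:
                weights = np.full(len(row_ids), 1.0 / len(row_ids))
            else:
                weights = weights_from_similarity(
                    [s for s in scores if s.other_subject in set(train_ids)], row_ids)
            ts, held_X, held_y = mix_budget(
                crowd_X, crowd_y, weights, row_ids, test_X, test_y,
                test_subject, fraction, basis=cfg.budget_basis)
            model = train_personalized(ts, cfg.model)
    except SingleClassError as exc:
        logger.warning("fold %s skipped: %s", test_subject, exc)
        return FoldResult(test_subject, None, None, 0, skipped=True, reason=str(exc))
    if len(held_y) == 0:
        return FoldResult(test_subject, None, None, 0, skipped=True,
                          reason="no held-out rows to evaluate")
    pred = model.predict(held_X)
    counts = confusion(held_y, pred)
    return FoldResult(test_subject, metrics(counts), counts, len(held_y), model=model)


def _aggregate(folds: Sequence[FoldResult]) -> tuple[MetricsReport, MetricsReport]:
    live = [f for f in folds if not f.skipped]
    if not live:
        raise ValidationError("every fold was skipped; nothing to aggregate")
    arrays = {
        name: np.array([getattr(f.report, name) for f in live])
        for name in ("accuracy", "precision", "recall", "f1")
    }
    mean = MetricsReport(**{k: float(v.mean()) for k, v in arrays.items()})
    ci = MetricsReport(**{
        k: float(1.96 * v.std(ddof=1) / math.sqrt(len(v))) if len(v) > 1 else 0.0
        for k, v in arrays.items()
    })
    return mean, ci


def loocv(features: pd.DataFrame, traits: Mapping[str, PhysicalTraits], cfg: PipelineConfig,
          mode: str = "personalized", fraction: float = 0.0,
          subjects: Sequence[str] | None = None) -> LoocvResult:
    """Leave-one-subject-out evaluation: every subject is the test fold once."""
    all_subjects = sorted(features["subject_id"].unique())
    if len(all_subjects) < 2:
        raise ValidationError("LOOCV needs at least 2 subjects")
    fold_subjects = sorted(subjects) if subjects is not None else all_subjects
    folds = [run_fold(features, traits, s, cfg, mode, fraction) for s in fold_subjects]
    mean, ci = _aggregate(folds)
    return LoocvResult(folds, mean, ci, n_skipped=sum(f.skipped for f in folds))


@dataclass
class SweepResult:
    """Per-grid-point mean accuracies (fractions), deltas vs the reference
    point, and the selected optimum per variant (lowest value on ties)."""

    grid: np.ndarray
    accuracies: dict[str, np.ndarray]
    deltas: dict[str, np.ndarray]
    best: dict[str, float]


def sweep_gamma(features: pd.DataFrame, traits: Mapping[str, PhysicalTraits],
                grid: Sequence[float], cfg: PipelineConfig,
                subjects: Sequence[str] | None = None) -> SweepResult:
    """Mean LOOCV accuracy of the physical-only and signal-only variants per
    gamma; deltas are measured against the gamma = 0 reference point."""
    grid = np.asarray(sorted(grid), dtype=float)
    if len(grid) == 0:
        raise ValidationError("gamma grid must be non-empty")
    if grid[0] != 0.0:
        raise ValidationError("gamma grid must include the reference point 0")
    variants = {"physical": (1.0, 0.0), "signal": (0.0, 1.0)}
    accuracies = {v: np.empty(len(grid)) for v in variants}
    for i, gamma in enumerate(grid):
        for variant, (alpha, beta) in variants.items():
            params = SimilarityParams(alpha=alpha, beta=beta, gamma=float(gamma))
            result = loocv(features, traits, cfg.with_params(params),
                           mode="personalized", subjects=subjects)
            accuracies[variant][i] = result.mean.accuracy
    deltas = {v: acc - acc[0] for v, acc in accuracies.items()}
    best = {v: float(grid[int(np.argmax(acc))]) for v, acc in accuracies.items()}
    return SweepResult(grid, accuracies, deltas, best)


def sweep_alpha_beta(features: pd.DataFrame, traits: Mapping[str, PhysicalTraits],
                     step: float, cfg: PipelineConfig,
                     subjects: Sequence[str] | None = None) -> SweepResult:
    """Mean LOOCV accuracy along the alpha + beta = 1 line, endpoints included."""
    if step <= 0:
        raise ValidationError("step must be positive")
    n_steps = round(1.0 / step)
    if abs(n_steps * step - 1.0) > 1e-9:
        raise ValidationError(f"step {step} does not divide 1 exactly")
    grid = np.round(np.linspace(0.0, 1.0, n_steps + 1), 10)
    accuracies = np.empty(len(grid))
    for i, alpha in enumerate(grid):
        params = SimilarityParams(alpha=float(alpha), beta=float(1.0 - alpha),
                                  gamma=cfg.params.gamma)
        result = loocv(features, traits, cfg.with_params(params),
                       mode="personalized", subjects=subjects)
        accuracies[i] = result.mean.accuracy
    deltas = accuracies - accuracies[0]
    best_alpha = float(grid[int(np.argmax(accuracies))])
    return SweepResult(grid, {"alpha": accuracies}, {"alpha": deltas}, {"alpha": best_alpha})


@dataclass
class BudgetRun:
    """One row of the budget experiment (percent scale for accuracy fields)."""

    fraction: float
    n_reps: int
    accuracy: float  # percent; NaN when the family is undefined at this run
    delta_accuracy: float | None  # percentage points vs the previous run
    agr: float | None  # percentage points per repetition

    def __post_init__(self) -> None:
        if self.delta_accuracy is not None and self.n_reps > 0 and self.agr is not None:
            if abs(self.agr * self.n_reps - self.delta_accuracy) > 1e-9:
                raise ValidationError("agr * n_reps must equal delta_accuracy")


DEFAULT_FRACTIONS = (0.0, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


def budget_curve(features: pd.DataFrame, traits: Mapping[str, PhysicalTraits],
                 cfg: PipelineConfig, fractions: Sequence[float] = DEFAULT_FRACTIONS,
                 subjects: Sequence[str] | None = None) -> dict[str, list[BudgetRun]]:
    """Accuracy / delta / AGR per incremental test-subject budget, for the
    subject-specific and personalized families, averaged over held-out subjects."""
    fractions = list(fractions)
    if fractions != sorted(fractions) or fractions[0] != 0.0:
        raise ValidationError("fractions must be ascending and start at 0")
    out: dict[str, list[BudgetRun]] = {}
    for family, mode in (("subject_specific", "specific"), ("personalized", "personalized")):
        runs: list[BudgetRun] = []
        prev_accuracy: float | None = None
        for f in fractions:
            n_reps = budget_to_repetitions(f, cfg.budget_basis)
            try:
                result = loocv(features, traits, cfg, mode=mode, fraction=f, subjects=subjects)
                accuracy = result.mean.accuracy * 100.0
            except ValidationError:
                accuracy = float("nan")
            if prev_accuracy is None or math.isnan(accuracy) or math.isnan(prev_accuracy):
                delta, agr = None, None
            else:
                delta = accuracy - prev_accuracy
                agr = accuracy_gain_ratio(delta, n_reps) if n_reps > 0 else None
            runs.append(BudgetRun(f, n_reps, accuracy, delta, agr))
            prev_accuracy = accuracy
        out[family] = runs
    return out


def budget_table(curves: Mapping[str, Sequence[BudgetRun]]) -> pd.DataFrame:
    """Flatten budget runs into the report layout (one row per family/run)."""
    rows = []
    for family, runs in curves.items():
        for run in runs:
            rows.append({
                "family": family, "fraction": run.fraction, "n_reps": run.n_reps,
                "accuracy": run.accuracy, "delta_accuracy": run.delta_accuracy,
                "agr": run.agr,
            })
    return pd.DataFrame(rows)
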