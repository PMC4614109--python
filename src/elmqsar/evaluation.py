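"""Confusion-matrix metrics, stratified k-fold CV, repeated experiments.

The positive class is *active* (code 1).  Metrics follow the standard
percentage formulas

    Sen  = TP / (TP + FN) * 100
    Spec = TN / (TN + FP) * 100
    Acc  = (TP + TN) / (TP + TN + FP + FN) * 100

and the Matthews correlation coefficient

    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

defined as 0 when the denominator vanishes.  Cross-validation is
stratified by class so every training and validation fold contains both
classes (a threshold needs both class means).  The repeated-experiment
harness reruns the full train + 10-fold-CV protocol R times with
consecutive seeds and reports per-run rows plus mean and sample standard
deviation of each metric, the layout used to summarise stochastic
training runs.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .data_model import ACTIVE, INACTIVE, LabeledDataset
from .errors import DegenerateProblemError, UnknownLabelError

logger = logging.getLogger(__name__)

# a trainer maps (training dataset, seed) -> an object with .predict(matrix)
Trainer = Callable[[LabeledDataset, int], object]

METRIC_NAMES = ("acc", "sen", "spec", "mcc")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp,
            self.tn + other.tn,
            self.fp + other.fp,
            self.fn + other.fn,
        )


@dataclass(frozen=True)
class MetricsReport:
    """Acc/Sen/Spec as percentages in [0, 100]; MCC in [-1, 1]."""

    acc: float
    sen: float
    spec: float
    mcc: float
    counts: ConfusionCounts

    def to_dict(self) -> dict:
        return {
            "acc": self.acc,
            "sen": self.sen,
            "spec": self.spec,
            "mcc": self.mcc,
            "tp": self.counts.tp,
            "tn": self.counts.tn,
            "fp": self.counts.fp,
            "fn": self.counts.fn,
        }


def confusion(predicted: Sequence[int], truth: Sequence[int]) -> ConfusionCounts:
    """Count TP/TN/FP/FN with active (1) as the positive class."""
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("predicted and true labels differ in length")
    for arr, name in ((pred, "predicted"), (true, "true")):
        bad = set(np.unique(arr)) - {ACTIVE, INACTIVE}
        if bad:
            raise UnknownLabelError(f"{name} labels outside {{1, 2}}: {sorted(bad)}")
    tp = int(np.sum((pred == ACTIVE) & (true == ACTIVE)))
    tn = int(np.sum((pred == INACTIVE) & (true == INACTIVE)))
    fp = int(np.sum((pred == ACTIVE) & (true == INACTIVE)))
    fn = int(np.sum((pred == INACTIVE) & (true == ACTIVE)))
    return ConfusionCounts(tp, tn, fp, fn)


def metrics(counts: ConfusionCounts) -> MetricsReport:
    """Acc/Sen/Spec/MCC from confusion counts.

    A metric whose denominator is zero is reported as 0 (documented
    convention; in particular MCC = 0 when any marginal is empty).
    """
    if counts.total == 0:
        raise DegenerateProblemError("no compounds evaluated")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn

    def ratio(num: float, den: float) -> float:
        return 100.0 * num / den if den > 0 else 0.0

    acc = ratio(tp + tn, counts.total)
    sen = ratio(tp, tp + fn)
    spec = ratio(tn, tn + fp)
    denom = math.sqrt(
        float(tp + fp) * float(tp + fn) * float(tn + fp) * float(tn + fn)
    )
    mcc = (tp * tn - fp * fn) / denom if denom > 0 else 0.0
    return MetricsReport(acc, sen, spec, mcc, counts)


def evaluate_predictions(predicted, truth) -> MetricsReport:
    return metrics(confusion(predicted, truth))


@dataclass
class CVResult:
    """Stratified k-fold cross-validation outcome.

    ``fold_assignments`` maps each compound to its fold index (1..k).
    ``pooled`` aggregates the confusion counts of all validation
    predictions; ``fold_average`` is the unweighted mean of the per-fold
    metrics (the "averaged across the validated subsets" convention).
    """

    fold_assignments: np.ndarray
    per_fold: list[MetricsReport]
    pooled: MetricsReport
    fold_average: dict[str, float]
    seed: int

    @property
    def k(self) -> int:
        return len(self.per_fold)

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "seed": self.seed,
            "fold_assignments": self.fold_assignments.tolist(),
            "per_fold": [m.to_dict() for m in self.per_fold],
            "pooled": self.pooled.to_dict(),
            "fold_average": self.fold_average,
        }


def kfold_cv(
    dataset: LabeledDataset,
    trainer: Trainer,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold cross-validation of a full training procedure.

    For each fold the trainer is fitted on the other k-1 folds only (all
    preprocessing included) and evaluated on the held-out fold, so no
    validation compound influences its own model.
    """
    n_active, n_inactive = dataset.class_counts()
    if min(n_active, n_inactive) < k:
        raise DegenerateProblemError(
            f"each class needs >= k={k} members "
            f"(active={n_active}, inactive={n_inactive})"
        )
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignments = np.zeros(dataset.n_compounds, dtype=int)
    per_fold: list[MetricsReport] = []
    pooled_counts = ConfusionCounts(0, 0, 0, 0)
    dummy = np.zeros(dataset.n_compounds)
    for fold, (train_idx, valid_idx) in enumerate(
        splitter.split(dummy, dataset.labels), start=1
    ):
        assignments[valid_idx] = fold
        model = trainer(dataset.take(train_idx), seed * 1000 + fold)
        valid = dataset.take(valid_idx)
        pred = model.predict(valid.matrix)
        report = evaluate_predictions(pred, valid.labels)
        per_fold.append(report)
        pooled_counts = pooled_counts + report.counts
    if np.any(assignments == 0):
        raise AssertionError("fold assignment is not a partition")
    fold_average = {
        name: float(np.mean([getattr(m, name) for m in per_fold]))
        for name in METRIC_NAMES
    }
    return CVResult(
        fold_assignments=assignments,
        per_fold=per_fold,
        pooled=metrics(pooled_counts),
        fold_average=fold_average,
        seed=seed,
    )


@dataclass
class ExperimentRun:
    run_index: int
    seed: int
    train_report: MetricsReport
    cv: CVResult

    def to_dict(self) -> dict:
        return {
            "run": self.run_index,
            "seed": self.seed,
            "train": self.train_report.to_dict(),
            "cv_pooled": self.cv.pooled.to_dict(),
            "cv_fold_average": self.cv.fold_average,
        }


@dataclass
class ExperimentSummary:
    """R repeats of the train + k-fold-CV protocol with mean +/- sd rows."""

    runs: list[ExperimentRun]
    train_mean: dict[str, float]
    train_sd: dict[str, float]
    cv_mean: dict[str, float]
    cv_sd: dict[str, float]
    best_run_index: int = 0

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    def to_dict(self) -> dict:
        return {
            "n_runs": self.n_runs,
            "runs": [r.to_dict() for r in self.runs],
            "train_mean": self.train_mean,
            "train_sd": self.train_sd,
            "cv_mean": self.cv_mean,
            "cv_sd": self.cv_sd,
            "best_run": self.best_run_index,
        }


def _mean_sd(values: list[float]) -> tuple[float, float]:
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1)) if len(values) > 1 else 0.0
    return mean, sd


def repeat_experiments(
    dataset: LabeledDataset,
    trainer: Trainer,
    R: int = 10,
    k: int = 10,
    base_seed: int = 0,
) -> ExperimentSummary:
    """Run the full train + k-fold-CV protocol R times.

    Run r uses seed ``base_seed + r`` for both the trainer and the fold
    randomisation, so every run re-randomises both.  The best run is the
    one with the highest pooled CV MCC.
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    runs: list[ExperimentRun] = []
    for r in range(R):
        seed = base_seed + r
        model = trainer(dataset, seed)
        train_report = evaluate_predictions(
            model.predict(dataset.matrix), dataset.labels
        )
        cv = kfold_cv(dataset, trainer, k=k, seed=seed)
        runs.append(ExperimentRun(r + 1, seed, train_report, cv))
        logger.info(
            "run %d/%d: train acc %.2f, CV acc %.2f (pooled)",
            r + 1, R, train_report.acc, cv.pooled.acc,
        )
    train_stats = {
        name: _mean_sd([getattr(run.train_report, name) for run in runs])
        for name in METRIC_NAMES
    }
    cv_stats = {
        name: _mean_sd([run.cv.pooled.__getattribute__(name) for run in runs])
        for name in METRIC_NAMES
    }
    best = max(runs, key=lambda run: run.cv.pooled.mcc)
    return ExperimentSummary(
        runs=runs,
        train_mean={k_: v[0] for k_, v in train_stats.items()},
        train_sd={k_: v[1] for k_, v in train_stats.items()},
        cv_mean={k_: v[0] for k_, v in cv_stats.items()},
        cv_sd={k_: v[1] for k_, v in cv_stats.items()},
        best_run_index=best.run_index,
    )
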