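"""Stratified splitting, confusion-matrix metrics, ROC/AUC and benchmarking.

The evaluation design mirrors a single seeded 80:20 train/test split shared
by every method, with the allergen class positive.  Precision is
TP/(TP+FP), recall TP/(TP+FN) and F1 their harmonic mean; ROC curves sweep
the unique score thresholds descending (ties grouped), making the
trapezoidal AUC equal to the tie-corrected concordance probability that a
random allergen outranks a random non-allergen.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.model_selection import train_test_split

from .acc import DEFAULT_MAX_LAG, FeatureMatrix, featurize_dataset
from .descriptors import EDescriptorTable
from .io import SequenceDataset
from .models import (ClassifierSpec, labels_to_binary, predict_labels,
                     predict_proba, train)


@dataclass(frozen=True)
class DatasetSplit:
    train_indices: np.ndarray
    test_indices: np.ndarray
    ratio: float
    seed: int
    stratified: bool

    def __post_init__(self) -> None:
        train, test = set(self.train_indices.tolist()), set(self.test_indices.tolist())
        if train & test:
            raise ValueError("train and test indices overlap")


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class MetricsRow:
    accuracy: float
    precision: float
    recall: float
    f1: float
    degenerate: tuple[str, ...] = ()


@dataclass(frozen=True)
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def stratified_split(labels, ratio: float = 0.8, seed: int = 0,
                     stratified: bool = True) -> DatasetSplit:
    """Seeded train/test index split; per-class balance kept within 1 sample."""
    y = np.asarray(labels)
    if not 0 < ratio < 1:
        raise ValueError(f"ratio must be in (0, 1), got {ratio}")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"expected binary labels, got classes {classes.tolist()}")
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples to split")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=ratio, random_state=seed,
        stratify=y if stratified else None, shuffle=True,
    )
    return DatasetSplit(train_indices=np.sort(train_idx),
                        test_indices=np.sort(test_idx),
                        ratio=ratio, seed=seed, stratified=stratified)


def confusion_counts(true_labels, predicted_labels) -> ConfusionCounts:
    """TP/FP/FN/TN with allergen (1) positive; accepts 0/1 or label strings."""
    y_true = _as_binary(true_labels, "true_labels")
    y_pred = _as_binary(predicted_labels, "predicted_labels")
    if len(y_true) != len(y_pred):
        raise ValueError(
            f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def _as_binary(labels, what: str) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        arr = labels_to_binary([str(x) for x in arr])
    arr = arr.astype(int)
    if not set(np.unique(arr).tolist()) <= {0, 1}:
        raise ValueError(f"{what} must be binary (0/1 or class-label strings)")
    return arr


def compute_metrics(counts: ConfusionCounts) -> MetricsRow:
    """Accuracy, precision, recall and (precision-based harmonic-mean) F1.

    Undefined ratios — no predicted positives, or no actual positives — are
    reported as 0 and flagged in ``degenerate`` rather than raising.
    """
    if counts.total == 0:
        raise ValueError("cannot compute metrics from empty counts")
    degenerate: list[str] = []
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        precision, _ = 0.0, degenerate.append("precision")
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        recall, _ = 0.0, degenerate.append("recall")
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    f1 = f1_from_precision_recall(precision, recall)
    return MetricsRow(accuracy=accuracy, precision=precision, recall=recall,
                      f1=f1, degenerate=tuple(degenerate))


def f1_from_precision_recall(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall; 0 when both vanish."""
    if precision + recall == 0:
        return 0.0
    return 2 * precision * recall / (precision + recall)


def roc_and_auc(true_labels, scores) -> ROCCurve:
    """ROC by descending unique-score thresholds (ties grouped) + trapezoid AUC."""
    y_true = _as_binary(true_labels, "true_labels")
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("ROC needs at least one positive and one negative")
    fpr, tpr, thresholds = _sk_roc_curve(y_true, scores, drop_intermediate=False)
    return ROCCurve(thresholds=thresholds, fpr=fpr, tpr=tpr,
                    auc=float(_trapezoid_auc(fpr, tpr)))


@dataclass
class MethodResult:
    kind: str
    seed: int
    hyperparams: dict
    train_accuracy: float
    test_metrics: MetricsRow
    auc: float


@dataclass
class EvaluationReport:
    """Per-method benchmark results on one shared seeded split."""

    results: list[MethodResult]
    split: dict
    max_lag: int
    dialect: str
    n_samples: int
    best_method: str
    roc_points: dict = field(default_factory=dict)  # fpr/tpr/thresholds of best method

    def to_json(self, path: str | os.PathLike | None = None) -> str:
        payload = {
            "split": self.split,
            "max_lag": self.max_lag,
            "dialect": self.dialect,
            "n_samples": self.n_samples,
            "best_method": self.best_method,
            "results": [
                {
                    "kind": r.kind, "seed": r.seed, "hyperparams": r.hyperparams,
                    "train_accuracy": r.train_accuracy,
                    "test_accuracy": r.test_metrics.accuracy,
                    "precision": r.test_metrics.precision,
                    "recall": r.test_metrics.recall,
                    "f1": r.test_metrics.f1,
                    "auc": r.auc,
                }
                for r in self.results
            ],
            "roc_points": {k: list(v) for k, v in self.roc_points.items()},
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "EvaluationReport":
        with open(path) as fh:
            payload = json.load(fh)
        results = [
            MethodResult(
                kind=r["kind"], seed=r["seed"], hyperparams=r["hyperparams"],
                train_accuracy=r["train_accuracy"],
                test_metrics=MetricsRow(
                    accuracy=r["test_accuracy"], precision=r["precision"],
                    recall=r["recall"], f1=r["f1"]),
                auc=r["auc"],
            )
            for r in payload["results"]
        ]
        return cls(results=results, split=payload["split"],
                   max_lag=payload["max_lag"], dialect=payload["dialect"],
                   n_samples=payload["n_samples"],
                   best_method=payload["best_method"],
                   roc_points={k: np.asarray(v) for k, v in payload["roc_points"].items()})

    def to_text(self) -> str:
        """Human-readable table: accuracies in percent, fractions to 2 dp."""
        lines = [
            f"{'method':<18}{'train_acc%':>11}{'test_acc%':>11}"
            f"{'precision':>11}{'recall':>8}{'F1':>6}{'AUC':>7}",
        ]
        for r in self.results:
            m = r.test_metrics
            lines.append(
                f"{r.kind:<18}{100 * r.train_accuracy:>11.2f}"
                f"{100 * m.accuracy:>11.2f}{m.precision:>11.2f}"
                f"{m.recall:>8.2f}{m.f1:>6.2f}{r.auc:>7.3f}"
            )
        lines.append(f"best method by AUC: {self.best_method}")
        return "\n".join(lines)


def evaluate_features(features: FeatureMatrix, specs: list[ClassifierSpec],
                      ratio: float = 0.8, seed: int = 0,
                      stratified: bool = True) -> EvaluationReport:
    """Benchmark already-featurized data: one shared split, one row per spec."""
    if features.labels is None:
        raise ValueError("benchmark requires labels")
    y = labels_to_binary(features.labels)
    split = stratified_split(y, ratio=ratio, seed=seed, stratified=stratified)
    train_fm = features.subset(split.train_indices)
    test_fm = features.subset(split.test_indices)
    y_test = labels_to_binary(test_fm.labels)
    results: list[MethodResult] = []
    roc_by_kind: dict[str, ROCCurve] = {}
    for spec in specs:
        try:
            model = train(spec, train_fm)
            scores = predict_proba(model, test_fm)
            preds = predict_labels(model, test_fm)
        except Exception as exc:
            raise RuntimeError(f"method {spec.kind!r} failed: {exc}") from exc
        counts = confusion_counts(y_test, preds)
        metrics = compute_metrics(counts)
        roc = roc_and_auc(y_test, scores)
        roc_by_kind[spec.kind] = roc
        results.append(MethodResult(
            kind=spec.kind, seed=spec.seed,
            hyperparams=model.training_meta["hyperparams"],
            train_accuracy=model.training_meta["training_accuracy"],
            test_metrics=metrics, auc=roc.auc,
        ))
    best = max(results, key=lambda r: r.auc)
    best_roc = roc_by_kind[best.kind]
    return EvaluationReport(
        results=results,
        split={"ratio": ratio, "seed": seed, "stratified": stratified,
               "n_train": int(len(split.train_indices)),
               "n_test": int(len(split.test_indices))},
        max_lag=-1,  # unknown here; benchmark() fills it in
        dialect="precomputed",
        n_samples=features.n_samples,
        best_method=best.kind,
        roc_points={"fpr": best_roc.fpr, "tpr": best_roc.tpr,
                    "thresholds": best_roc.thresholds},
    )


def benchmark(dataset: SequenceDataset, specs: list[ClassifierSpec],
              table: EDescriptorTable, max_lag: int = DEFAULT_MAX_LAG,
              dialect: str = "uncentered", ratio: float = 0.8, seed: int = 0,
              stratified: bool = True,
              short_policy: str = "error") -> EvaluationReport:
    """Full pipeline benchmark: featurize once, share one split across methods."""
    features = featurize_dataset(dataset, table, max_lag=max_lag, dialect=dialect,
                                 short_policy=short_policy)
    report = evaluate_features(features, specs, ratio=ratio, seed=seed,
                               stratified=stratified)
    report.max_lag = max_lag
    report.dialect = dialect
    return report
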