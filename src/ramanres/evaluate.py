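"""Classification metrics for the tumor-vs-normal task.

Accuracy, precision, recall and F1 are computed from the confusion counts
with predicted-positive defined as probability >= threshold (ties count as
positive, matching the sigmoid-0.5 convention).  The ROC curve is built
over all distinct score thresholds with tied scores sharing one vertex, and
the AUC is its trapezoidal area

    AUC = 1/2 * sum_i (TPR_{i+1} + TPR_i) (FPR_{i+1} - FPR_i),

which under this tie handling equals the Mann-Whitney pair statistic with
half credit for ties.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .preprocess import PreprocessedMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "MetricsReport",
    "RocCurve",
    "confusion_counts",
    "compute_metrics",
    "roc_auc",
    "evaluate_model",
    "evaluate_probabilities",
    "run_baseline_classifiers",
]


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float
    recall: float
    f1: float
    threshold: float = 0.5
    auc: Optional[float] = None

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def confusion_matrix(self) -> np.ndarray:
        """Rows = true class (normal, tumor); columns = predicted class."""
        return np.array([[self.tn, self.fp], [self.fn, self.tp]])

    def to_dict(self) -> dict:
        d = {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1, "threshold": self.threshold,
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def to_json(self, path) -> None:
        from pathlib import Path

        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


@dataclass
class RocCurve:
    thresholds: np.ndarray  # descending
    tpr: np.ndarray
    fpr: np.ndarray

    def to_csv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(
            {"threshold": self.thresholds, "fpr": self.fpr, "tpr": self.tpr}
        ).to_csv(path, index=False)


def confusion_counts(
    y_true: Sequence[int], y_prob: Sequence[float], threshold: float = 0.5
) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) with predicted positive iff probability >= threshold."""
    y = np.asarray(y_true)
    p = np.asarray(y_prob, dtype=float)
    if y.size == 0:
        raise ValueError("empty input")
    if y.shape != p.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {p.shape}")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    pred = p >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    return tp, fp, tn, fn


def compute_metrics(
    counts: tuple[int, int, int, int], threshold: float = 0.5
) -> MetricsReport:
    """Accuracy, precision, recall, F1 from (tp, fp, tn, fn).

    Metrics with a zero denominator are reported as 0 (logged), so batch
    evaluation never produces NaN.
    """
    tp, fp, tn, fn = (int(v) for v in counts)
    total = tp + fp + tn + fn
    if total <= 0:
        raise ValueError("counts sum to zero")

    def ratio(num: int, den: int, name: str) -> float:
        if den == 0:
            logger.info("metric %s has zero denominator; reporting 0", name)
            return 0.0
        return num / den

    return MetricsReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total,
        precision=ratio(tp, tp + fp, "precision"),
        recall=ratio(tp, tp + fn, "recall"),
        f1=ratio(2 * tp, 2 * tp + fn + fp, "f1"),
        threshold=threshold,
    )


def roc_auc(y_true: Sequence[int], y_score: Sequence[float]) -> tuple[RocCurve, float]:
    """ROC curve over all distinct thresholds and its trapezoidal AUC."""
    y = np.asarray(y_true)
    s = np.asarray(y_score, dtype=float)
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("roc_auc needs both classes present")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    # one vertex per distinct score (ties grouped), plus the (0,0) origin
    distinct = np.flatnonzero(np.r_[True, np.diff(s_sorted) != 0])
    tp_cum = np.cumsum(y_sorted == 1)
    fp_cum = np.cumsum(y_sorted == 0)
    last = np.r_[distinct[1:] - 1, y.size - 1]
    tpr = np.r_[0.0, tp_cum[last] / n_pos]
    fpr = np.r_[0.0, fp_cum[last] / n_neg]
    thresholds = np.r_[np.inf, s_sorted[distinct]]
    auc = 0.5 * float(np.sum((tpr[1:] + tpr[:-1]) * (fpr[1:] - fpr[:-1])))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr), auc


def evaluate_probabilities(
    y_true: Sequence[int], y_prob: Sequence[float], threshold: float = 0.5
) -> MetricsReport:
    """Full report (counts, derived metrics, AUC) from scores."""
    counts = confusion_counts(y_true, y_prob, threshold)
    report = compute_metrics(counts, threshold)
    y = np.asarray(y_true)
    if 0 < np.sum(y == 1) < y.size:
        _, report.auc = roc_auc(y_true, y_prob)
    return report


def evaluate_model(
    predictor, matrix: PreprocessedMatrix, threshold: float = 0.5
) -> MetricsReport:
    """Evaluate anything that maps spectra to tumor probabilities.

    ``predictor`` may be a callable on the (N, channels) value matrix, an
    object with ``predict_proba`` (ensemble or network), or a network whose
    ``predict_proba`` takes raw values.
    """
    if matrix.labels is None:
        raise ValueError("evaluation requires labels")
    if callable(predictor):
        probs = predictor(matrix.values)
    else:
        try:
            probs = predictor.predict_proba(matrix)
        except (TypeError, ValueError):
            probs = predictor.predict_proba(matrix.values)
    probs = np.asarray(probs, dtype=float)
    if probs.ndim == 2:  # sklearn-style (N, 2) probabilities
        probs = probs[:, 1]
    return evaluate_probabilities(matrix.labels, probs, threshold)


def _default_baselines(seed: int) -> dict[str, Callable[[], object]]:
    def svm():
        from sklearn.svm import SVC

        return SVC(kernel="linear", probability=True, random_state=seed)

    def random_forest():
        from sklearn.ensemble import RandomForestClassifier

        return RandomForestClassifier(n_estimators=200, random_state=seed)

    def xgboost():
        from xgboost import XGBClassifier

        return XGBClassifier(
            n_estimators=200, max_depth=4, random_state=seed, verbosity=0
        )

    def lightgbm():
        from lightgbm import LGBMClassifier

        return LGBMClassifier(n_estimators=200, random_state=seed, verbose=-1)

    return {
        "svm": svm,
        "random_forest": random_forest,
        "xgboost": xgboost,
        "lightgbm": lightgbm,
    }


def run_baseline_classifiers(
    matrix: PreprocessedMatrix,
    split: tuple[np.ndarray, np.ndarray, np.ndarray],
    baseline_set: Optional[Iterable[str]] = None,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict[str, dict[str, MetricsReport]]:
    """Comparison harness: fit off-the-shelf classifiers on the flattened
    channel rows and evaluate with the same metrics on the validation and
    test partitions.  Unavailable backends are skipped with a warning."""
    if matrix.labels is None:
        raise ValueError("baseline harness requires labels")
    tr, va, te = (np.asarray(s) for s in split)
    factories = _default_baselines(seed)
    names = list(baseline_set) if baseline_set is not None else list(factories)
    out: dict[str, dict[str, MetricsReport]] = {}
    for name in names:
        if name not in factories:
            raise ValueError(f"unknown baseline {name!r}; known: {sorted(factories)}")
        try:
            clf = factories[name]()
        except ImportError as exc:
            warnings.warn(f"baseline {name!r} unavailable ({exc}); skipped")
            continue
        clf.fit(matrix.values[tr], matrix.labels[tr])
        reports = {}
        for part, idx in (("val", va), ("test", te)):
            probs = clf.predict_proba(matrix.values[idx])[:, 1]
            reports[part] = evaluate_probabilities(matrix.labels[idx], probs, threshold)
        out[name] = reports
    return out
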