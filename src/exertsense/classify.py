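"""Quadratic-kernel SVM exertion detector and its metric suite.

The detector is the classic "quadratic SVM" preset: features standardized
per column (parameters learned on training rows only), a degree-2 polynomial
kernel with unit regularization constant, and stratified 5-fold
cross-validated training accuracy as the model-selection response. The
positive class is 1 (exertion).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import WindowSpec, feature_columns
from .io import ExertionIntervals


def _make_estimator() -> Pipeline:
    return Pipeline([
        ("scale", StandardScaler()),
        ("svm", SVC(kernel="poly", degree=2, coef0=1.0, gamma="scale", C=1.0,
                    cache_size=256)),
    ])


@dataclass
class MetricsReport:
    """Confusion counts with class 1 (exertion) positive, plus the derived
    accuracy / precision / recall / F1 (all in percent)."""

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def accuracy(self) -> float:
        return 100.0 * (self.tp + self.tn) / self.n if self.n else 0.0

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return 100.0 * self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return 100.0 * self.tp / d if d else 0.0

    @property
    def f1(self) -> float:
        return f1_from_precision_recall(self.precision, self.recall)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fn": self.fn, "fp": self.fp, "tn": self.tn,
            "accuracy": self.accuracy, "precision": self.precision,
            "recall": self.recall, "f1": self.f1,
        }

    def summary(self) -> str:
        return (
            f"confusion matrix (positive = exertion):\n"
            f"  TP={self.tp}  FN={self.fn}\n"
            f"  FP={self.fp}  TN={self.tn}\n"
            f"accuracy  {self.accuracy:6.2f} %\n"
            f"precision {self.precision:6.2f} %\n"
            f"recall    {self.recall:6.2f} %\n"
            f"F1 score  {self.f1:6.2f} %"
        )


def f1_from_precision_recall(precision_pct: float, recall_pct: float) -> float:
    """Harmonic mean of precision and recall, in percent."""
    if precision_pct + recall_pct == 0:
        return 0.0
    return 2 * precision_pct * recall_pct / (precision_pct + recall_pct)


def evaluate(truth: np.ndarray, predicted: np.ndarray) -> MetricsReport:
    """Confusion counts and derived metrics for labels in {1, 2}."""
    truth = np.asarray(truth)
    predicted = np.asarray(predicted)
    if truth.shape != predicted.shape:
        raise ValueError("truth and predicted labels must have equal length")
    for arr, name in ((truth, "truth"), (predicted, "predicted")):
        if not np.isin(arr, (1, 2)).all():
            raise ValueError(f"{name} labels must be in {{1, 2}}")
    tp = int(np.sum((truth == 1) & (predicted == 1)))
    fn = int(np.sum((truth == 1) & (predicted == 2)))
    fp = int(np.sum((truth == 2) & (predicted == 1)))
    tn = int(np.sum((truth == 2) & (predicted == 2)))
    return MetricsReport(tp=tp, fn=fn, fp=fp, tn=tn)


class ExertionQSVM:
    """Quadratic-kernel SVM exertion model built from a feature table.

    Parameters
    ----------
    table : DataFrame
        Windows x features table with a ``label`` column in {1, 2}.
    feature_cols : list of str, optional
        Feature columns to use; defaults to every non-metadata column.

    ``fit`` returns an :class:`ExertionQSVMResults` carrying the
    cross-validated training accuracy and the refitted model.
    """

    def __init__(self, table: pd.DataFrame, feature_cols: list[str] | None = None,
                 label_col: str = "label"):
        self.table = table
        self.feature_cols = feature_cols if feature_cols is not None else feature_columns(table)
        self.label_col = label_col

    @classmethod
    def from_dataframe(cls, table: pd.DataFrame, **kwargs) -> "ExertionQSVM":
        return cls(table, **kwargs)

    def fit(self, folds: int = 5, seed: int = 0) -> "ExertionQSVMResults":
        X = self.table[self.feature_cols].to_numpy(dtype=float)
        y = self.table[self.label_col].to_numpy()
        if not np.isfinite(X).all():
            raise ValueError("feature table contains non-finite values")
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training table contains a single class")
        if counts.min() < folds:
            raise ValueError(
                f"need >= {folds} rows of each class, got counts {dict(zip(classes, counts))}")
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
        scores = cross_val_score(_make_estimator(), X, y, cv=cv, scoring="accuracy")
        model = _make_estimator().fit(X, y)
        return ExertionQSVMResults(
            model=model, cv_accuracy=float(scores.mean()), cv_fold_scores=scores,
            feature_cols=list(self.feature_cols), label_col=self.label_col,
            folds=folds, seed=seed, n_rows=len(y),
        )


@dataclass
class ExertionQSVMResults:
    """Fitted exertion detector with its cross-validation diagnostics."""

    model: Pipeline
    cv_accuracy: float           # mean stratified k-fold accuracy, 0..1
    cv_fold_scores: np.ndarray
    feature_cols: list[str]
    label_col: str
    folds: int
    seed: int
    n_rows: int

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        """Predict {1, 2} labels for the rows of a feature table."""
        missing = [c for c in self.feature_cols if c not in table.columns]
        if missing:
            raise ValueError(f"feature table lacks training-time columns {missing}")
        return self.model.predict(table[self.feature_cols].to_numpy(dtype=float))

    def evaluate(self, table: pd.DataFrame) -> MetricsReport:
        """Confusion-matrix metrics against the table's own labels."""
        return evaluate(table[self.label_col].to_numpy(), self.predict(table))

    def summary(self) -> str:
        lines = [
            "Quadratic-kernel SVM exertion detector",
            f"  training rows        {self.n_rows}",
            f"  features             {len(self.feature_cols)}",
            f"  CV folds (stratified) {self.folds}, seed {self.seed}",
            f"  CV training accuracy {100 * self.cv_accuracy:.2f} %",
            "  fold accuracies      " + ", ".join(f"{100 * s:.2f}" for s in self.cv_fold_scores),
        ]
        return "\n".join(lines)


def windows_to_intervals(predicted: np.ndarray, window_starts: np.ndarray,
                         spec: WindowSpec = WindowSpec()) -> ExertionIntervals:
    """Merge runs of consecutive exertion-labeled windows into sample
    intervals (for rendering predictions against the ground truth)."""
    predicted = np.asarray(predicted)
    window_starts = np.asarray(window_starts)
    if predicted.shape != window_starts.shape:
        raise ValueError("one label per window start is required")
    intervals: list[tuple[int, int]] = []
    run_start = None
    prev_end = None
    for lab, start in zip(predicted, window_starts):
        if lab == 1:
            if run_start is None:
                run_start = int(start)
            prev_end = int(start) + spec.size
        else:
            if run_start is not None:
                intervals.append((run_start, prev_end))
                run_start = None
    if run_start is not None:
        intervals.append((run_start, prev_end))
    # overlapping windows can make adjacent runs touch; merge defensively
    merged: list[tuple[int, int]] = []
    for s, e in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return ExertionIntervals(merged, provenance="predicted")
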