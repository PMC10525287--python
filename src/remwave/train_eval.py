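"""Trainer/tester: stratified cross-validation and confusion metrics.

REM is the positive class throughout.  Per fold the tester records the
raw confusion counts (true REM, false REM, false non-REM, true non-REM)
and derives

* accuracy   = (tp + tn) / (tp + fp + fn + tn)
* specificity = tn / (tn + fp)
* recall (sensitivity) = tp / (tp + fn)
* precision  = tp / (tp + fp)
* f1         = 2 * precision * recall / (precision + recall)

with zero-denominator cases returning 0 under a logged warning.  The
cross-validation report averages each metric unweighted across folds.
The batch size, when not given, is derived from the record count R, the
validation split V and the fold count C as ``int(R * (1 - V) / C + 1)``
(one batch spanning the whole training portion of a fold).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import clone
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

logger = logging.getLogger(__name__)

__all__ = [
    "TrainingConfig",
    "FitHistory",
    "FoldResult",
    "CVReport",
    "derive_batch_size",
    "stratified_folds",
    "train_fold",
    "evaluate_fold",
    "aggregate",
    "cross_validate",
    "compute_stream_metrics",
]

METRIC_NAMES = ("accuracy", "specificity", "recall", "precision", "f1")


def derive_batch_size(R: int, V: float, C: int) -> int:
    """Batch size covering one fold's full training portion.

    ``int(R * (1 - V) / C + 1)`` with truncation toward zero.
    """
    if R < 1:
        raise ValueError(f"record count must be >= 1, got {R}")
    return int((R * (1.0 - V)) / C + 1)


@dataclass
class TrainingConfig:
    """Cross-validation and fitting parameters."""

    cv_folds: int = 10
    validation_split: float = 0.1
    max_epochs: int = 100
    record_count: int | None = None
    batch_size: int | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.validation_split < 1.0:
            raise ValueError(f"validation_split outside (0,1): {self.validation_split}")
        if self.cv_folds < 2:
            raise ValueError(f"cv_folds must be >= 2, got {self.cv_folds}")

    def resolved_batch_size(self, n_records: int | None = None) -> int:
        if self.batch_size is not None:
            return self.batch_size
        R = self.record_count if n_records is None else n_records
        if R is None:
            raise ValueError("record_count needed to derive the batch size")
        return derive_batch_size(R, self.validation_split, self.cv_folds)


class FitHistory:
    """Per-epoch training/validation metric rows."""

    def __init__(self, rows: list[dict] | None = None):
        self.rows: list[dict] = rows or []

    def append(self, row: dict):
        self.rows.append(row)

    def __len__(self) -> int:
        return len(self.rows)

    def last(self, key: str, default=float("nan")) -> float:
        for row in reversed(self.rows):
            if key in row:
                return row[key]
        return default

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)


def compute_stream_metrics(y01, p_pos) -> dict:
    """Threshold (0.5) and ranking metrics for one data stream.

    ``y01``: 0/1 labels with REM = 1; ``p_pos``: predicted REM
    probability.  AUC over a single-class stream is undefined and
    reported as the chance value 0.5.
    """
    y01 = np.asarray(y01)
    yhat = (np.asarray(p_pos) >= 0.5).astype(int)
    tp = int(np.sum((yhat == 1) & (y01 == 1)))
    fp = int(np.sum((yhat == 1) & (y01 == 0)))
    fn = int(np.sum((yhat == 0) & (y01 == 1)))
    tn = int(np.sum((yhat == 0) & (y01 == 0)))
    m = _metrics_from_counts(tp, fp, fn, tn, warn=False)
    if len(np.unique(y01)) < 2:
        auc = 0.5
    else:
        auc = float(roc_auc_score(y01, p_pos))
    return {
        "accuracy": m["accuracy"],
        "precision": m["precision"],
        "recall": m["recall"],
        "f1": m["f1"],
        "auc_roc": auc,
    }


def _safe_div(num, den, name, warn=True):
    if den == 0:
        if warn:
            logger.warning("metric %s has zero denominator; reporting 0", name)
        return 0.0
    return num / den


def _metrics_from_counts(tp, fp, fn, tn, warn=True) -> dict:
    accuracy = _safe_div(tp + tn, tp + fp + fn + tn, "accuracy", warn)
    specificity = _safe_div(tn, tn + fp, "specificity", warn)
    recall = _safe_div(tp, tp + fn, "recall", warn)
    precision = _safe_div(tp, tp + fp, "precision", warn)
    f1 = _safe_div(2 * precision * recall, precision + recall, "f1", warn)
    return {
        "accuracy": accuracy,
        "specificity": specificity,
        "recall": recall,
        "precision": precision,
        "f1": f1,
    }


@dataclass
class FoldResult:
    """Confusion counts and derived metrics for one test fold (REM positive)."""

    tp: int
    fp: int
    fn: int
    tn: int
    accuracy: float = field(init=False)
    specificity: float = field(init=False)
    recall: float = field(init=False)
    precision: float = field(init=False)
    f1: float = field(init=False)
    last_loss: float = float("nan")

    def __post_init__(self):
        m = _metrics_from_counts(self.tp, self.fp, self.fn, self.tn)
        self.accuracy = m["accuracy"]
        self.specificity = m["specificity"]
        self.recall = m["recall"]
        self.precision = m["precision"]
        self.f1 = m["f1"]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CVReport:
    """All fold results plus their unweighted metric means."""

    folds: list

    @property
    def averages(self) -> dict:
        return aggregate_metrics(self.folds)

    def to_dict(self) -> dict:
        return {"folds": [f.to_dict() for f in self.folds], "averages": self.averages}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def save(self, path):
        Path(path).write_text(self.to_json(), encoding="utf-8")

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame([f.to_dict() for f in self.folds])
        df.index = np.arange(1, len(df) + 1)
        return df


def aggregate_metrics(folds: list[FoldResult]) -> dict:
    if not folds:
        raise ValueError("need at least one fold")
    out = {}
    for name in ("tp", "fp", "fn", "tn") + METRIC_NAMES:
        out[name] = float(np.mean([getattr(f, name) for f in folds]))
    return out


def aggregate(folds: list[FoldResult]) -> CVReport:
    """Wrap fold results in a report with unweighted metric averages."""
    if not folds:
        raise ValueError("need at least one fold")
    return CVReport(folds=list(folds))


def stratified_folds(labels, C: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified k-fold index pairs preserving the REM/non-REM ratio."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("stratified folds need both classes present")
    if C > counts.min():
        raise ValueError(
            f"cv_folds={C} exceeds minority class count {counts.min()}"
        )
    skf = StratifiedKFold(n_splits=C, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def train_fold(model, train_data, config: TrainingConfig):
    """Fit a (cloned) estimator on one fold's training data.

    Returns ``(fitted_model, FitHistory)``.  The estimator's own
    ``validation_split``/``max_epochs``/``batch_size`` are set from the
    config; stopping is driven by validation loss inside ``fit``.
    """
    X, y = train_data
    if len(np.unique(np.asarray(y))) < 2:
        raise ValueError("training fold has a single class; cannot stratify validation")
    m = clone(model)
    m.set_params(
        validation_split=config.validation_split,
        max_epochs=config.max_epochs,
        batch_size=config.resolved_batch_size(len(y)),
    )
    m.fit(X, y)
    return m, m.history_


def evaluate_fold(model, test_data) -> FoldResult:
    """Confusion counts and metrics on one test fold (REM positive)."""
    X, y = test_data
    y = np.asarray(y)
    pred = model.predict(X)
    pos = getattr(model, "positive_class_", "REM")
    tp = int(np.sum((pred == pos) & (y == pos)))
    fp = int(np.sum((pred == pos) & (y != pos)))
    fn = int(np.sum((pred != pos) & (y == pos)))
    tn = int(np.sum((pred != pos) & (y != pos)))
    last_loss = float("nan")
    history = getattr(model, "history_", None)
    if history is not None and len(history):
        last_loss = history.last("loss")
    return FoldResult(tp=tp, fp=fp, fn=fn, tn=tn, last_loss=last_loss)


def cross_validate(model, X, y, config: TrainingConfig) -> CVReport:
    """Full stratified C-fold cross-validation of an estimator."""
    X = np.asarray(X)
    y = np.asarray(y)
    folds = stratified_folds(y, config.cv_folds, config.seed)
    results = []
    for k, (tr, te) in enumerate(folds):
        fitted, _hist = train_fold(model, (X[tr], y[tr]), config)
        results.append(evaluate_fold(fitted, (X[te], y[te])))
        logger.info("fold %d/%d: %s", k + 1, config.cv_folds, results[-1])
    return aggregate(results)
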