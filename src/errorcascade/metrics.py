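"""Confusion-matrix metrics, rank-based AUC and repeated stratified k-fold CV.

Recall is TP/(TP+FN), precision TP/(TP+FP) and the F-measure their harmonic
mean; all are reported for the positive class (outcome 1).  AUC uses the
Mann-Whitney rank formulation with ties counted one half, which equals the
trapezoidal area under the ROC curve.  The CV harness runs stratified
k-fold ``repeats`` times with reshuffled folds and evaluates every model
on identical folds, yielding k x repeats metric records per model.
"""

from __future__ import annotations

import dataclasses
import warnings

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .data import RecordTable, smote_balance
from .learners import positive_score


@dataclasses.dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def confusion(y_true, y_pred, positive_label: int = 1) -> ConfusionMatrix:
    """Tally the 2x2 confusion matrix for the stated positive label."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} contains labels outside {{0, 1}}")
    pos_t = y_true == positive_label
    pos_p = y_pred == positive_label
    return ConfusionMatrix(
        tp=int((pos_t & pos_p).sum()),
        fp=int((~pos_t & pos_p).sum()),
        tn=int((~pos_t & ~pos_p).sum()),
        fn=int((pos_t & ~pos_p).sum()),
    )


def _safe_ratio(num: int, den: int, what: str) -> float:
    if den == 0:
        warnings.warn(
            f"{what} denominator is zero; reporting 0", RuntimeWarning, stacklevel=3
        )
        return 0.0
    return num / den


def recall(cm: ConfusionMatrix) -> float:
    """True positive rate TP/(TP+FN)."""
    return _safe_ratio(cm.tp, cm.tp + cm.fn, "recall")


def precision(cm: ConfusionMatrix) -> float:
    """Positive predictive value TP/(TP+FP)."""
    return _safe_ratio(cm.tp, cm.tp + cm.fp, "precision")


def f_measure(p: float, r: float) -> float:
    """Harmonic mean 2PR/(P+R); 0 when both are 0."""
    if p + r == 0:
        return 0.0
    return 2.0 * p * r / (p + r)


def auc(y_true, scores) -> float:
    """Tie-adjusted probability a random positive outscores a random negative."""
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, float)
    if y_true.shape != scores.shape:
        raise ValueError("y_true and scores must have equal length")
    n_pos = int((y_true == 1).sum())
    n_neg = int((y_true == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes in y_true")
    ranks = rankdata(scores)  # average ranks handle ties at 1/2
    rank_sum = ranks[y_true == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


@dataclasses.dataclass(frozen=True)
class MetricsRecord:
    model: str
    repeat: int
    fold: int
    recall: float
    precision: float
    f_measure: float
    auc: float


@dataclasses.dataclass(frozen=True)
class CVResult:
    k: int
    repeats: int
    seed: int
    records: tuple[MetricsRecord, ...]
    fold_assignments: dict[int, np.ndarray]  # repeat -> fold id per instance


def evaluate_predictions(y_true, y_pred, scores) -> dict[str, float]:
    """Positive-class recall/precision/F and AUC for one evaluation set."""
    cm = confusion(y_true, y_pred)
    r = recall(cm)
    p = precision(cm)
    return {
        "recall": r,
        "precision": p,
        "f_measure": f_measure(p, r),
        "auc": auc(y_true, scores),
    }


def repeated_kfold(
    table: RecordTable,
    model_factories: dict,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
    smote: bool = False,
    smote_k: int = 5,
) -> CVResult:
    """Repeated stratified k-fold CV over a set of model factories.

    Every factory is a zero-argument callable returning an unfitted
    estimator; all models are trained and scored on identical folds.
    Folds are reshuffled per repeat from seeds ``seed, seed+1, ...``.
    When ``smote`` is set the minority class is oversampled inside each
    training fold only, never in the test fold.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    counts = np.bincount(table.labels, minlength=2)
    if counts.min() < k:
        raise ValueError(
            f"smallest class has {counts.min()} records; cannot stratify into {k} folds"
        )
    records: list[MetricsRecord] = []
    fold_assignments: dict[int, np.ndarray] = {}
    for rep in range(repeats):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + rep)
        assignment = np.full(table.n, -1, dtype=int)
        folds = list(splitter.split(table.features, table.labels))
        for fold_id, (_, test_idx) in enumerate(folds):
            assignment[test_idx] = fold_id
        fold_assignments[rep] = assignment
        for fold_id, (train_idx, test_idx) in enumerate(folds):
            train = table.take(train_idx)
            if smote:
                train = smote_balance(
                    train, k_neighbors=smote_k, seed=seed + rep * k + fold_id
                ).table
            test = table.take(test_idx)
            for name, factory in model_factories.items():
                model = factory()
                model.fit(train.features, train.labels)
                y_pred = np.asarray(model.predict(test.features))
                scores = positive_score(model, test.features)
                m = evaluate_predictions(test.labels, y_pred, scores)
                records.append(
                    MetricsRecord(
                        model=name, repeat=rep, fold=fold_id, **m
                    )
                )
    return CVResult(k, repeats, seed, tuple(records), fold_assignments)


def summarize(result: CVResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-model mean/SD summary plus a long per-run table for boxplots."""
    if not result.records:
        raise ValueError("empty CV result")
    long = pd.DataFrame(
        [
            {
                "model": rec.model,
                "metric": metric,
                "repeat": rec.repeat,
                "fold": rec.fold,
                "value": getattr(rec, metric),
            }
            for rec in result.records
            for metric in ("recall", "precision", "f_measure", "auc")
        ]
    )
    summary = (
        long.groupby(["model", "metric"])["value"]
        .agg(mean="mean", sd=lambda v: v.std(ddof=1))
        .reset_index()
    )
    return summary, long
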