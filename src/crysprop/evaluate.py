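"""Performance measures and analyses: the six evaluation metrics
(accuracy, MCC, sensitivity, specificity, precision, AUC), ROC curves, a
stratified cross-validation harness, inter-task output correlations, and
per-feature contribution scores (t-test significance and single-feature
AUC)."""

from __future__ import annotations

import dataclasses
import math
from typing import Callable, Mapping

import numpy as np
from scipy import stats as _stats
from sklearn.model_selection import StratifiedKFold


class EvaluationError(ValueError):
    pass


@dataclasses.dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise EvaluationError("confusion counts must be non-negative")
        if self.tp + self.fp + self.tn + self.fn < 1:
            raise EvaluationError("confusion counts are all zero")


@dataclasses.dataclass(frozen=True)
class MetricSet:
    accuracy: float
    mcc: float
    sensitivity: float
    specificity: float
    precision: float
    auc: float | None = None
    degenerate: tuple[str, ...] = ()


def confusion_metrics(counts: ConfusionCounts) -> MetricSet:
    """Accuracy, MCC, sensitivity, specificity and precision from counts.
    A zero denominator yields 0 for that metric, flagged in ``degenerate``."""
    tp, fp, tn, fn = counts.tp, counts.fp, counts.tn, counts.fn
    total = tp + fp + tn + fn
    degenerate = []

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            degenerate.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    mcc_den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = ratio(tp * tn - fp * fn, mcc_den, "mcc")
    return MetricSet(
        accuracy=accuracy,
        mcc=mcc,
        sensitivity=sensitivity,
        specificity=specificity,
        precision=precision,
        degenerate=tuple(degenerate),
    )


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based (Mann-Whitney) AUC with half-credit for ties; equals the
    trapezoidal area under the ROC curve."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise EvaluationError("AUC requires both classes present")
    ranks = _stats.rankdata(scores)  # average ranks handle ties
    rank_sum = ranks[labels == 1].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def roc_curve(scores: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """ROC points ((FPR, TPR) from (0,0) to (1,1)) and thresholds."""
    from sklearn.metrics import roc_curve as _sk_roc

    fpr, tpr, thresholds = _sk_roc(labels, scores, drop_intermediate=False)
    return fpr, tpr, thresholds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    trainer: Callable[[np.ndarray, np.ndarray], object],
    folds: int = 5,
    seed: int = 0,
) -> tuple[list[MetricSet], float, np.ndarray]:
    """Stratified k-fold evaluation of a trainer returning probability
    models; each row is scored exactly once out-of-fold.  Returns per-fold
    metric sets (threshold 0.5), the pooled out-of-fold AUC and the pooled
    out-of-fold score vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < folds:
        raise EvaluationError(
            f"need at least {folds} rows per class, have {counts.tolist()}"
        )
    oof = np.empty(len(y))
    per_fold: list[MetricSet] = []
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in skf.split(X, y):
        model = trainer(X[train_idx], y[train_idx])
        scores = np.asarray(model.predict_proba(X[test_idx]), dtype=float)
        if scores.ndim == 2:
            scores = scores[:, -1]
        oof[test_idx] = scores
        pred = (scores >= 0.5).astype(int)
        truth = y[test_idx]
        cm = ConfusionCounts(
            tp=int(((pred == 1) & (truth == 1)).sum()),
            fp=int(((pred == 1) & (truth == 0)).sum()),
            tn=int(((pred == 0) & (truth == 0)).sum()),
            fn=int(((pred == 0) & (truth == 1)).sum()),
        )
        metrics = confusion_metrics(cm)
        fold_auc = auc(scores, truth) if len(np.unique(truth)) == 2 else None
        per_fold.append(dataclasses.replace(metrics, auc=fold_auc))
    return per_fold, auc(oof, y), oof


def output_correlation_matrix(meta: np.ndarray) -> np.ndarray:
    """Pearson correlations of the five per-task probability columns
    (symmetric, unit diagonal; zero-variance columns yield NaN rows)."""
    meta = np.asarray(meta, dtype=float)
    if meta.shape[0] < 3:
        raise EvaluationError("need at least 3 rows for correlations")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(meta, rowvar=False)
    np.fill_diagonal(corr, 1.0)
    return corr


def feature_significance(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-feature -log10 p from a two-sample unequal-variance t-test;
    degenerate (zero-variance) features get p = 1."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    pos, neg = X[y == 1], X[y == 0]
    if len(pos) < 2 or len(neg) < 2:
        raise EvaluationError("need at least 2 rows per class")
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = _stats.ttest_ind(pos, neg, equal_var=False)
    pvals = np.where(np.isfinite(pvals), pvals, 1.0)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)
    return -np.log10(pvals)


def single_feature_auc(X: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-feature AUC using the feature itself as the score.  Returns
    (raw, oriented) where oriented = max(AUC, 1-AUC)."""
    X = np.asarray(X, dtype=float)
    raw = np.array([auc(X[:, j], y) for j in range(X.shape[1])])
    return raw, np.maximum(raw, 1.0 - raw)


def correlation_with_tasks(
    meta_or_model, table=None
) -> np.ndarray:
    """Convenience wrapper: accept either a meta matrix or a stacked model
    plus feature table and return the 5x5 output correlation matrix."""
    if table is not None:
        meta = meta_or_model.predict_level1(table)
    else:
        meta = meta_or_model
    return output_correlation_matrix(meta)
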