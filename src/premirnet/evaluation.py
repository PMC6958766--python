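"""Classification metrics, ROC/PRC curves, and CV aggregation.

Internal values are fractions; conversion to percentages happens only at
presentation (``as_percent``) to avoid double scaling.  A score exactly
at the threshold counts as a positive call, matching the prediction
writer's tie rule.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValidationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class EvalMetrics:
    sensitivity: float
    specificity: float
    f1: float
    mcc: float
    accuracy: float

    FIELDS = ("sensitivity", "specificity", "f1", "mcc", "accuracy")

    def as_percent(self) -> dict:
        return {k: getattr(self, k) * 100.0 for k in self.FIELDS}


@dataclass(frozen=True)
class CurveSeries:
    thresholds: tuple[float, ...]
    points: tuple[tuple[float, float], ...]
    auc: float


@dataclass(frozen=True)
class CVSummary:
    per_fold: tuple[EvalMetrics, ...]
    mean: dict
    se: dict


def confusion(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Tally a confusion matrix at a probability threshold (>= is positive)."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValidationError("labels and scores must have equal length")
    if labels.size == 0:
        raise ValidationError("cannot tally an empty evaluation set")
    if (scores < 0).any() or (scores > 1).any():
        raise ValidationError("scores must lie in [0, 1]")
    pred = scores >= threshold
    truth = labels == 1
    return ConfusionCounts(
        tp=int((pred & truth).sum()),
        tn=int((~pred & ~truth).sum()),
        fp=int((pred & ~truth).sum()),
        fn=int((~pred & truth).sum()),
    )


def metrics(c: ConfusionCounts) -> EvalMetrics:
    """Sensitivity, specificity, F1, MCC and accuracy from the counts.

    Zero-denominator conventions: MCC is 0; sensitivity/specificity/F1
    are NaN (undefined).
    """
    if c.total == 0:
        raise ValidationError("confusion counts are all zero")
    tp, tn, fp, fn = c.tp, c.tn, c.fp, c.fn
    sens = tp / (tp + fn) if (tp + fn) else math.nan
    spec = tn / (tn + fp) if (tn + fp) else math.nan
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else math.nan
    denom = math.sqrt((tp + fn) * (tn + fp) * (tn + fn) * (tp + fp))
    mcc = (tp * tn - fp * fn) / denom if denom else 0.0
    acc = (tp + tn) / c.total
    return EvalMetrics(sensitivity=sens, specificity=spec, f1=f1, mcc=mcc, accuracy=acc)


def roc_prc(labels, scores) -> tuple[CurveSeries, CurveSeries]:
    """ROC and precision-recall curves over every distinct score threshold.

    Thresholds descend; the ROC starts at (0,0), the PRC at recall 0
    with precision 1 by convention.  Both AUCs use the trapezoidal rule.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape or labels.size == 0:
        raise ValidationError("labels and scores must be non-empty and equal length")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValidationError("both classes must be present to draw curves")

    thresholds = np.unique(scores)[::-1]
    roc_points = [(0.0, 0.0)]
    prc_points = [(0.0, 1.0)]
    order = np.argsort(-scores, kind="stable")
    sorted_labels = labels[order]
    sorted_scores = scores[order]
    tp = fp = 0
    i = 0
    for t in thresholds:
        while i < len(sorted_scores) and sorted_scores[i] >= t:
            if sorted_labels[i] == 1:
                tp += 1
            else:
                fp += 1
            i += 1
        roc_points.append((fp / n_neg, tp / n_pos))
        prc_points.append((tp / n_pos, tp / (tp + fp)))

    def _trap(points):
        xs = np.array([p[0] for p in points])
        ys = np.array([p[1] for p in points])
        return float(np.trapezoid(ys, xs))

    roc = CurveSeries(tuple(thresholds), tuple(roc_points), _trap(roc_points))
    prc = CurveSeries(tuple(thresholds), tuple(prc_points), _trap(prc_points))
    return roc, prc


def summarize_cv(per_fold) -> CVSummary:
    """Per-metric mean and standard error (sample SD / sqrt(k)) over folds."""
    per_fold = tuple(per_fold)
    k = len(per_fold)
    if k < 2:
        raise ValidationError("need at least 2 folds to summarize")
    mean, se = {}, {}
    for name in EvalMetrics.FIELDS:
        vals = np.array([getattr(m, name) for m in per_fold], dtype=float)
        mean[name] = float(vals.mean())
        se[name] = float(vals.std(ddof=1) / np.sqrt(k))
    return CVSummary(per_fold=per_fold, mean=mean, se=se)


@dataclass(frozen=True)
class SpeciesReport:
    """A cross-species prediction row: all inputs assumed true precursors."""

    species: str
    n: int
    n_correct: int

    @property
    def accuracy_percent(self) -> float:
        return 100.0 * self.n_correct / self.n

    def as_row(self) -> dict:
        return {
            "species": self.species,
            "n_pre_mirnas": self.n,
            "n_correct_prediction": self.n_correct,
            "accuracy_percent": round(self.accuracy_percent, 2),
        }


def species_report(classifier, table, species: str = "unknown",
                   alphabet=None, max_len: int | None = None) -> SpeciesReport:
    """Fraction of an (assumed all-positive) table called positive at 0.5."""
    from .encoding import DEFAULT_ALPHABET, DEFAULT_MAX_LEN, encode_record
    from .models import positive_scores

    if len(table) == 0:
        raise ValidationError("empty table")
    alphabet = alphabet or DEFAULT_ALPHABET
    max_len = max_len or DEFAULT_MAX_LEN
    mats = [encode_record(r, alphabet, max_len) for r in table]
    scores = positive_scores(classifier, mats)
    return SpeciesReport(
        species=species, n=len(table), n_correct=int((scores >= 0.5).sum())
    )
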