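"""Evaluation metrics and the stratified cross-validation driver.

ACC, SN (lncRNA recall), SP, PRE and F1 follow the usual confusion-count
definitions; a metric whose denominator is zero is reported as NaN
("undefined") rather than coerced to 0. AUC is the area under the ROC
curve with tied scores rank-averaged (Mann-Whitney normalization).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields
from typing import Callable, Optional

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    tn: int
    fp: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @classmethod
    def from_predictions(cls, truth, predicted) -> "ConfusionCounts":
        truth = np.asarray(truth)
        predicted = np.asarray(predicted)
        return cls(
            tp=int(np.sum((truth == 1) & (predicted == 1))),
            fn=int(np.sum((truth == 1) & (predicted == 0))),
            tn=int(np.sum((truth == 0) & (predicted == 0))),
            fp=int(np.sum((truth == 0) & (predicted == 1))),
        )


@dataclass(frozen=True)
class MetricsReport:
    """AUC/ACC/SN/SP/PRE/F1; NaN marks an undefined metric."""

    auc: float
    acc: float
    sn: float
    sp: float
    pre: float
    f1: float

    def as_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _ratio(num: float, den: float) -> float:
    return num / den if den > 0 else math.nan


def auc_score(truth, scores) -> float:
    """ROC AUC (tie-averaged); NaN when a class is absent."""
    truth = np.asarray(truth)
    if len(np.unique(truth)) < 2:
        return math.nan
    return float(roc_auc_score(truth, scores))


def compute_metrics(
    counts: ConfusionCounts,
    scores=None,
    truth=None,
) -> MetricsReport:
    """Threshold metrics from counts; AUC from (truth, scores) if given."""
    tp, fn, tn, fp = counts.tp, counts.fn, counts.tn, counts.fp
    acc = _ratio(tp + tn, tp + tn + fp + fn)
    sn = _ratio(tp, tp + fn)
    sp = _ratio(tn, tn + fp)
    pre = _ratio(tp, tp + fp)
    if math.isnan(pre) or math.isnan(sn) or (pre + sn) == 0:
        f1 = math.nan
    else:
        f1 = 2.0 * pre * sn / (pre + sn)
    auc = math.nan
    if scores is not None and truth is not None:
        auc = auc_score(truth, scores)
    return MetricsReport(auc=auc, acc=acc, sn=sn, sp=sp, pre=pre, f1=f1)


def cross_validate(
    X,
    y,
    model_factory: Callable,
    folds: int = 10,
    seed: int = 0,
    threshold: float = 0.5,
) -> dict:
    """Seeded stratified k-fold CV of a score-producing classifier.

    ``model_factory()`` must return a fresh estimator with ``fit`` and
    either ``predict_score`` or ``predict_proba``. Returns per-fold
    reports, their (NaN-aware) mean, and a pooled report over the
    concatenated held-out predictions.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=seed % (2**31))
    per_fold: list[MetricsReport] = []
    all_scores = np.empty(len(y))
    all_truth = np.empty(len(y), dtype=y.dtype)
    pos = 0
    pooled_counts = np.zeros(4, dtype=int)
    for tr, te in skf.split(X, y):
        model = model_factory()
        model.fit(X[tr], y[tr])
        if hasattr(model, "predict_score"):
            scores = np.asarray(model.predict_score(X[te]))
        else:
            proba = model.predict_proba(X[te])
            cls = list(getattr(model, "classes_"))
            scores = proba[:, cls.index(1)]
        pred = (scores >= threshold).astype(int)
        counts = ConfusionCounts.from_predictions(y[te], pred)
        per_fold.append(compute_metrics(counts, scores=scores, truth=y[te]))
        n = len(te)
        all_scores[pos : pos + n] = scores
        all_truth[pos : pos + n] = y[te]
        pos += n
        pooled_counts += [counts.tp, counts.fn, counts.tn, counts.fp]
    pooled = compute_metrics(
        ConfusionCounts(*map(int, pooled_counts)),
        scores=all_scores,
        truth=all_truth,
    )
    mean = MetricsReport(
        **{
            f.name: float(np.nanmean([getattr(r, f.name) for r in per_fold]))
            for f in fields(MetricsReport)
        }
    )
    return {"per_fold": per_fold, "mean": mean, "pooled": pooled}
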