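"""Confusion-matrix metrics and AUC for vessel probability maps.

Scoring is FOV-restricted by default: pixels outside the field-of-view
mask are excluded from the counts, matching the preprocessing step that
removes everything outside the retina.  Binarization uses a strict
``prob > threshold`` comparison.  Zero-denominator metrics are reported as
NaN with an explicit flag, never silently as 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .exceptions import ShapeError

__all__ = ["ConfusionCounts", "MetricReport", "confusion", "metrics", "auc",
           "evaluate_probabilities"]


@dataclass
class ConfusionCounts:
    tp: int = 0
    tn: int = 0
    fp: int = 0
    fn: int = 0

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricReport:
    sen: float
    spe: float
    acc: float
    f1: float
    auc: float = float("nan")
    scope: str = "patch"
    flags: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"sen": self.sen, "spe": self.spe, "acc": self.acc,
                "f1": self.f1, "auc": self.auc, "scope": self.scope}


def _validate(prob, truth, fov):
    prob = np.asarray(prob, dtype=np.float64)
    truth = np.asarray(truth)
    if truth.shape != prob.shape:
        raise ShapeError(f"probability {prob.shape} vs truth {truth.shape}")
    if fov is not None:
        fov = np.asarray(fov)
        if fov.shape != prob.shape:
            raise ShapeError(f"probability {prob.shape} vs fov {fov.shape}")
        keep = fov > 0
    else:
        keep = np.ones(prob.shape, dtype=bool)
    return prob[keep], truth[keep] > 0


def confusion(prob, truth, fov=None, threshold: float = 0.5
              ) -> ConfusionCounts:
    """Pixel confusion counts at a strict ``prob > threshold`` rule."""
    scores, labels = _validate(prob, truth, fov)
    pred = scores > threshold
    return ConfusionCounts(
        tp=int(np.sum(pred & labels)),
        tn=int(np.sum(~pred & ~labels)),
        fp=int(np.sum(pred & ~labels)),
        fn=int(np.sum(~pred & labels)),
    )


def metrics(counts: ConfusionCounts, scope: str = "patch") -> MetricReport:
    """Sensitivity, specificity, accuracy and F1 from confusion counts.

    sen = tp/(tp+fn); spe = tn/(tn+fp); acc = (tp+tn)/total;
    f1 = 2tp/(2tp+fn+fp).  Undefined ratios (zero denominators) are NaN
    and recorded in ``flags``.
    """
    flags: dict = {}

    def ratio(num, den, name):
        if den == 0:
            flags[name] = "undefined (zero denominator)"
            return float("nan")
        return num / den

    sen = ratio(counts.tp, counts.tp + counts.fn, "sen")
    spe = ratio(counts.tn, counts.tn + counts.fp, "spe")
    acc = ratio(counts.tp + counts.tn, counts.total, "acc")
    f1 = ratio(2 * counts.tp, 2 * counts.tp + counts.fn + counts.fp, "f1")
    return MetricReport(sen=sen, spe=spe, acc=acc, f1=f1, scope=scope,
                        flags=flags)


def auc(prob, truth, fov=None) -> float:
    """Area under the ROC curve as the Mann-Whitney statistic.

    Equals the probability that a uniformly random vessel pixel scores
    higher than a random background pixel, counting ties as 1/2.  NaN when
    either class is absent inside the FOV.
    """
    scores, labels = _validate(prob, truth, fov)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return float("nan")
    ranks = stats.rankdata(scores)
    rank_sum = ranks[labels].sum()
    return float((rank_sum - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def evaluate_probabilities(prob, truth, fov=None, threshold: float = 0.5,
                           scope: str = "patch") -> MetricReport:
    """Full metric report (including AUC) for one probability map."""
    report = metrics(confusion(prob, truth, fov, threshold), scope=scope)
    report.auc = auc(prob, truth, fov)
    if np.isnan(report.auc):
        report.flags["auc"] = "undefined (one class absent)"
    return report
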