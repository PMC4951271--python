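"""Binary-classification scoring and per-feature class-separation statistics.

Six metrics over a confusion matrix with hot spots as the positive class:

    ACC = (TP+TN)/(TP+FP+TN+FN)        SPE = TN/(TN+FP)
    PRE = TP/(TP+FP)                   REC = TP/(TP+FN)
    F1  = 2·REC·PRE/(REC+PRE)
    MCC = (TP·TN − FP·FN)/√((TP+FN)(TP+FP)(TN+FP)(TN+FN))

Zero denominators follow the dominant convention: the affected metric is 0.
Feature separation between classes is summarised by per-class medians and a
two-sided Mann–Whitney U test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import UsageError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        for name in ("tp", "tn", "fp", "fn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise UsageError(f"{name} must be a non-negative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn,
                               self.fp + other.fp, self.fn + other.fn)


@dataclass(frozen=True)
class MetricSet:
    acc: float
    spe: float
    pre: float
    rec: float
    f1: float
    mcc: float

    def as_dict(self) -> dict[str, float]:
        return {"ACC": self.acc, "SPE": self.spe, "PRE": self.pre,
                "REC": self.rec, "F1": self.f1, "MCC": self.mcc}


def _ratio(num: float, den: float) -> float:
    return num / den if den else 0.0


def compute_metrics(counts: ConfusionCounts) -> MetricSet:
    """The six metrics; metrics with a zero denominator evaluate to 0."""
    if counts.total == 0:
        raise UsageError("all confusion counts are zero")
    tp, tn, fp, fn = counts.tp, counts.tn, counts.fp, counts.fn
    pre = _ratio(tp, tp + fp)
    rec = _ratio(tp, tp + fn)
    mcc_den = math.sqrt((tp + fn) * (tp + fp) * (tn + fp) * (tn + fn))
    return MetricSet(
        acc=_ratio(tp + tn, counts.total),
        spe=_ratio(tn, tn + fp),
        pre=pre,
        rec=rec,
        f1=_ratio(2 * rec * pre, rec + pre),
        mcc=(tp * tn - fp * fn) / mcc_den if mcc_den else 0.0,
    )


def confusion_from_labels(predicted, truth, positive="hot") -> ConfusionCounts:
    """Tally a confusion matrix from parallel label sequences."""
    predicted = np.asarray(predicted)
    truth = np.asarray(truth)
    if predicted.shape != truth.shape:
        raise UsageError(f"length mismatch: {predicted.shape} vs {truth.shape}")
    p = predicted == positive if predicted.dtype.kind in "UOS" else predicted.astype(bool)
    t = truth == positive if truth.dtype.kind in "UOS" else truth.astype(bool)
    return ConfusionCounts(tp=int(np.sum(p & t)), tn=int(np.sum(~p & ~t)),
                           fp=int(np.sum(p & ~t)), fn=int(np.sum(~p & t)))


def round_half_up(x: float, decimals: int = 2) -> float:
    """Display rounding used in report tables (0.005 -> 0.01)."""
    factor = 10 ** decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def metrics_report_row(counts: ConfusionCounts, name: str = "model") -> dict:
    """One evaluation-report row with 2-decimal half-up display rounding."""
    m = compute_metrics(counts)
    row = {"model": name, "TP": counts.tp, "TN": counts.tn,
           "FP": counts.fp, "FN": counts.fn}
    row.update({k: round_half_up(v, 2) for k, v in m.as_dict().items()})
    return row


def feature_separation_report(values, labels, positive="hot") -> dict:
    """Per-class medians and a two-sided Mann–Whitney U p-value.

    Small tie-free samples use the exact null distribution; larger or tied
    samples use the tie-corrected normal approximation.  If every
    observation shares one value the classes are indistinguishable and p=1.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    pos = values[labels == positive]
    neg = values[labels != positive]
    if len(pos) == 0 or len(neg) == 0:
        raise UsageError("both classes must be non-empty")
    if np.all(values == values[0]):
        return {"median_hot": float(values[0]), "median_nonhot": float(values[0]),
                "p_value": 1.0}
    res = stats.mannwhitneyu(pos, neg, alternative="two-sided", method="auto")
    return {"median_hot": float(np.median(pos)),
            "median_nonhot": float(np.median(neg)),
            "p_value": float(res.pvalue)}


def separation_table(features: pd.DataFrame, labels) -> pd.DataFrame:
    """Separation report for every feature column."""
    rows = {}
    for col in features.columns:
        rows[col] = feature_separation_report(features[col].to_numpy(), labels)
    return pd.DataFrame.from_dict(rows, orient="index")
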