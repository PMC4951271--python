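"""Two-step feature selection.

Step 1 ranks each feature group by greedy minimum-redundancy
maximum-relevance (mRMR, MID criterion) over mutual information of
3-state-discretised features, keeping the top third of every group
(17→6, 55→18, 33→11, 3→1 = 36 retained).  Step 2 is an SVM wrapper: every
pair of retained features is scored by pooled k-fold cross-validated F1
(MCC breaks ties), the best pair seeds a greedy forward search, and a
candidate is added only while F1 strictly improves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import CvConfig, SvmConfig, cross_validate
from .dataset import FEATURE_GROUPS, LabeledDataset
from .errors import DataError, UsageError
from .evaluation import compute_metrics

log = logging.getLogger(__name__)


def discretize(values) -> np.ndarray:
    """Three-state coding (0=low, 1=mid, 2=high) by z-score thresholds ±1.

    A constant column cannot be discretised informatively; it maps to
    all-mid with a warning.
    """
    x = np.asarray(values, dtype=float)
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        log.warning("constant column discretised to all-mid")
        return np.ones(len(x), dtype=np.int8)
    z = (x - x.mean()) / sd
    return (np.int8(1) + (z > 1).astype(np.int8) - (z < -1).astype(np.int8))


def mutual_information(x, y) -> float:
    """Plug-in mutual information (bits) between two discrete columns."""
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise UsageError(f"length mismatch: {x.shape} vs {y.shape}")
    if len(x) < 2:
        raise UsageError("need at least 2 samples")
    n = len(x)
    joint: dict[tuple, int] = {}
    for xi, yi in zip(x.tolist(), y.tolist()):
        joint[(xi, yi)] = joint.get((xi, yi), 0) + 1
    px: dict = {}
    py: dict = {}
    for (xi, yi), c in joint.items():
        px[xi] = px.get(xi, 0) + c
        py[yi] = py.get(yi, 0) + c
    mi = 0.0
    for (xi, yi), c in joint.items():
        p = c / n
        mi += p * math.log2(p * n * n / (px[xi] * py[yi]))
    return max(mi, 0.0)


def mrmr_rank(features: pd.DataFrame, labels) -> list[tuple[str, float]]:
    """Greedy mRMR ordering (MID: relevance minus mean redundancy).

    The first feature maximises I(f; y); each subsequent pick maximises
    I(f; y) − mean_{s in selected} I(f; s).  Returns (name, score) pairs in
    rank order; scores are the MID values at selection time.
    """
    if features.shape[1] == 0:
        raise UsageError("no features to rank")
    y = np.asarray(labels)
    disc = {c: discretize(features[c].to_numpy()) for c in features.columns}
    relevance = {c: mutual_information(disc[c], y) for c in features.columns}
    remaining = list(features.columns)
    ranked: list[tuple[str, float]] = []
    redundancy_sum = {c: 0.0 for c in remaining}
    while remaining:
        if not ranked:
            scores = {c: relevance[c] for c in remaining}
        else:
            k = len(ranked)
            scores = {c: relevance[c] - redundancy_sum[c] / k for c in remaining}
        # deterministic tie-break: score desc, then column order
        best = max(remaining, key=lambda c: (scores[c], -remaining.index(c)))
        ranked.append((best, scores[best]))
        remaining.remove(best)
        for c in remaining:
            redundancy_sum[c] += mutual_information(disc[c], disc[best])
    return ranked


def select_top_third(group_size: int) -> int:
    """Features retained per group: round-half-up(size/3), at least 1."""
    if group_size < 1:
        raise UsageError("group size must be >= 1")
    return max(1, math.floor(group_size / 3 + 0.5))


@dataclass
class SelectionResult:
    group_ranks: dict[str, list[tuple[str, float]]]
    retained: list[str]
    trace: pd.DataFrame
    final_subset: list[str]


def _cv_scores(dataset: LabeledDataset, subset: list[str],
               svm: SvmConfig, cv: CvConfig) -> tuple[float, float]:
    counts = cross_validate(dataset, subset, svm, cv)
    m = compute_metrics(counts)
    return m.f1, m.mcc


def wrapper_search(candidates: list[str], dataset: LabeledDataset,
                   cv: CvConfig = CvConfig(),
                   svm: SvmConfig = SvmConfig()) -> tuple[list[str], pd.DataFrame]:
    """Best-pair seeding plus greedy forward search under CV F1.

    All candidate pairs are evaluated; the winner (F1, then MCC, then
    candidate order) seeds the subset.  One feature is added per step —
    the addition with the best (F1, MCC) — and accepted only if CV F1
    strictly improves; otherwise the search stops.
    """
    if len(candidates) < 2:
        raise UsageError("need at least 2 candidate features")
    if len(set(np.asarray(dataset.labels))) < 2:
        raise DataError("dataset contains a single class")

    trace_rows = []
    best_pair, best_score = None, None
    for i in range(len(candidates)):
        for j in range(i + 1, len(candidates)):
            pair = [candidates[i], candidates[j]]
            score = _cv_scores(dataset, pair, svm, cv)
            if best_score is None or score > best_score:
                best_pair, best_score = pair, score
    subset = list(best_pair)
    f1, mcc = best_score
    trace_rows.append({"step": 0, "subset": "+".join(subset),
                       "cv_f1": f1, "cv_mcc": mcc, "accepted": True})

    step = 0
    while True:
        step += 1
        remaining = [c for c in candidates if c not in subset]
        if not remaining:
            break
        best_add, best_add_score = None, None
        for c in remaining:
            score = _cv_scores(dataset, subset + [c], svm, cv)
            if best_add_score is None or score > best_add_score:
                best_add, best_add_score = c, score
        add_f1, add_mcc = best_add_score
        accepted = add_f1 > f1
        trace_rows.append({"step": step, "subset": "+".join(subset + [best_add]),
                           "cv_f1": add_f1, "cv_mcc": add_mcc,
                           "accepted": accepted})
        if not accepted:
            break
        subset.append(best_add)
        f1, mcc = add_f1, add_mcc
        if f1 >= 1.0:
            break
    return subset, pd.DataFrame(trace_rows)


def two_step_select(dataset: LabeledDataset,
                    groups: dict[str, list[str]] | None = None,
                    cv: CvConfig = CvConfig(),
                    svm: SvmConfig = SvmConfig()) -> SelectionResult:
    """The full two-step selection over the four feature groups."""
    groups = FEATURE_GROUPS if groups is None else groups
    y = np.asarray(dataset.labels)
    group_ranks = {}
    retained: list[str] = []
    for name, columns in groups.items():
        columns = [c for c in columns if c in dataset.features.columns]
        ranked = mrmr_rank(dataset.features[columns], y)
        group_ranks[name] = ranked
        keep = select_top_third(len(columns))
        retained.extend(col for col, _ in ranked[:keep])
    subset, trace = wrapper_search(retained, dataset, cv, svm)
    return SelectionResult(group_ranks=group_ranks, retained=retained,
                           trace=trace, final_subset=subset)
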