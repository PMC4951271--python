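"""RBF-kernel SVM training, grid search, and pooled cross-validation.

The shipped defaults (C = 80.0, G = 0.002) are the grid-search optimum for
the three-feature hot-spot model; cross-validation uses stratified folds
with a fixed seed and pools out-of-fold predictions into one confusion
matrix, so class totals are conserved across folds.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import joblib
import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .dataset import HOT, NONHOT, ColumnTransform, LabeledDataset
from .errors import DataError, SchemaError, UsageError
from .evaluation import ConfusionCounts, compute_metrics

BUNDLE_FORMAT_VERSION = "hotspotter-model-1"

DEFAULT_C_GRID = (0.5, 1.0, 2.0, 5.0, 10.0, 20.0, 40.0, 80.0)
DEFAULT_G_GRID = (0.0005, 0.001, 0.002, 0.005, 0.01, 0.05, 0.1, 0.5, 1.0, 2.0)


@dataclass(frozen=True)
class SvmConfig:
    C: float = 80.0
    G: float = 0.002

    def __post_init__(self):
        if self.C <= 0 or self.G <= 0:
            raise UsageError("C and G must be positive")


@dataclass
class CvConfig:
    k: int = 10
    seed: int = 0


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise DataError("dataset contains a single class")


def _svc(config: SvmConfig) -> SVC:
    return SVC(kernel="rbf", C=config.C, gamma=config.G)


@dataclass
class ModelBundle:
    """A trained decision function plus everything needed to apply it."""

    svc: SVC
    features: list[str]
    transform: ColumnTransform
    config: SvmConfig
    training_fingerprint: str
    format_version: str = BUNDLE_FORMAT_VERSION

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        bundle = joblib.load(path)
        if getattr(bundle, "format_version", None) != BUNDLE_FORMAT_VERSION:
            raise SchemaError("unrecognised model bundle format")
        return bundle


def _fingerprint(x: pd.DataFrame, y: np.ndarray) -> str:
    h = hashlib.sha256()
    h.update(np.ascontiguousarray(x.to_numpy(float)).tobytes())
    h.update(np.ascontiguousarray(y.astype(np.int8)).tobytes())
    return h.hexdigest()[:16]


def train(dataset: LabeledDataset, features: list[str],
          config: SvmConfig = SvmConfig()) -> ModelBundle:
    """Fit the SVM on all rows; scaling/imputation are fitted here and frozen."""
    y = dataset.y
    _check_two_classes(y)
    if min(np.sum(y), np.sum(~y)) < 2:
        raise DataError("need >= 2 samples per class")
    missing = [f for f in features if f not in dataset.features.columns]
    if missing:
        raise SchemaError(f"training table lacks columns: {missing}")
    raw = dataset.features[features]
    transform = ColumnTransform.fit(raw)
    svc = _svc(config).fit(transform.apply(raw).to_numpy(), y.astype(int))
    return ModelBundle(svc=svc, features=list(features), transform=transform,
                       config=config, training_fingerprint=_fingerprint(raw, y))


def predict(bundle: ModelBundle, features: pd.DataFrame) -> pd.DataFrame:
    """Hot/non-hot labels with decision values for ranking."""
    missing = [f for f in bundle.features if f not in features.columns]
    if missing:
        raise SchemaError(f"feature table lacks columns: {missing}")
    x = bundle.transform.apply(features[bundle.features]).to_numpy()
    decision = bundle.svc.decision_function(x)
    labels = np.where(decision > 0, HOT, NONHOT)
    return pd.DataFrame({"label": labels, "decision_value": decision},
                        index=features.index)


def _fold_scale(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Median imputation + min-max scaling fitted on the training fold only.

    Numpy equivalent of :class:`ColumnTransform`, used on the CV hot path.
    """
    with np.errstate(all="ignore"):
        medians = np.nan_to_num(np.nanmedian(train, axis=0))
    train = np.where(np.isnan(train), medians, train)
    test = np.where(np.isnan(test), medians, test)
    lo, hi = train.min(axis=0), train.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    scale = lambda x: np.clip((x - lo) / span, 0.0, 1.0)
    return scale(train), scale(test)


def cross_validate(dataset: LabeledDataset, features: list[str],
                   config: SvmConfig = SvmConfig(),
                   cv: CvConfig = CvConfig()) -> ConfusionCounts:
    """Pooled confusion counts from stratified k-fold cross-validation.

    Scaling and imputation are re-fitted inside each training fold.
    """
    y = dataset.y
    _check_two_classes(y)
    minority = min(np.sum(y), np.sum(~y))
    if cv.k > minority:
        raise UsageError(f"k={cv.k} exceeds minority class size {minority}")
    if cv.k < 2:
        raise UsageError("k must be >= 2")
    raw = dataset.features[features].to_numpy(dtype=float)
    skf = StratifiedKFold(n_splits=cv.k, shuffle=True, random_state=cv.seed)
    pooled = ConfusionCounts(0, 0, 0, 0)
    for train_idx, test_idx in skf.split(raw, y):
        x_train, x_test = _fold_scale(raw[train_idx], raw[test_idx])
        svc = _svc(config).fit(x_train, y[train_idx].astype(int))
        pred = svc.predict(x_test).astype(bool)
        truth = y[test_idx]
        pooled = pooled + ConfusionCounts(
            tp=int(np.sum(pred & truth)), tn=int(np.sum(~pred & ~truth)),
            fp=int(np.sum(pred & ~truth)), fn=int(np.sum(~pred & truth)))
    return pooled


def grid_search(dataset: LabeledDataset, features: list[str],
                c_grid=DEFAULT_C_GRID, g_grid=DEFAULT_G_GRID,
                cv: CvConfig = CvConfig()) -> tuple[SvmConfig, pd.DataFrame]:
    """Best (C, G) by pooled CV F1; ties broken by MCC, then smaller C and G.

    Returns the winning configuration and the full CV table.
    """
    if not len(c_grid) or not len(g_grid):
        raise UsageError("grids must be non-empty")
    if any(v <= 0 for v in list(c_grid) + list(g_grid)):
        raise UsageError("grid values must be positive")
    rows = []
    for c in c_grid:
        for g in g_grid:
            config = SvmConfig(C=float(c), G=float(g))
            counts = cross_validate(dataset, features, config, cv)
            m = compute_metrics(counts)
            rows.append({"C": float(c), "G": float(g), "F1": m.f1, "MCC": m.mcc,
                         "ACC": m.acc, "TP": counts.tp, "TN": counts.tn,
                         "FP": counts.fp, "FN": counts.fn})
    table = pd.DataFrame(rows)
    best = max(range(len(rows)),
               key=lambda i: (rows[i]["F1"], rows[i]["MCC"],
                              -rows[i]["C"], -rows[i]["G"]))
    return SvmConfig(C=rows[best]["C"], G=rows[best]["G"]), table
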