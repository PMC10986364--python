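"""Repeated stratified k-fold cross-validation, confusion-matrix metrics,
and the KNN/SVM baselines evaluated on flattened 1-D feature vectors.

The reference protocol is five independent repetitions of stratified 5-fold
CV (25 train/test splits); per-fold z-scoring statistics are fit on that
fold's training rows only, so no information leaks from test to train.
Metrics: accuracy, sensitivity (recall of the preictal class), precision,
and specificity, reported as mean ± std over all folds.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .features import FeatureBlock
from .model import ModelConfig, SeizurePredictor
from .tensorize import (GridLayout, apply_scaler, fit_scaler, stack_samples,
                        assemble_tensor)

logger = logging.getLogger(__name__)

METRIC_NAMES = ("accuracy", "sensitivity", "precision", "specificity")


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def confusion_from_predictions(y_true, y_pred) -> ConfusionCounts:
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        TP=int(((y_true == 1) & (y_pred == 1)).sum()),
        TN=int(((y_true == 0) & (y_pred == 0)).sum()),
        FP=int(((y_true == 0) & (y_pred == 1)).sum()),
        FN=int(((y_true == 1) & (y_pred == 0)).sum()),
    )


def metrics(c: ConfusionCounts) -> dict[str, float | None]:
    """Acc, Sens, Prec, Spec from confusion counts.

    A metric whose denominator is zero is reported as None (undefined),
    with a warning — never silently as 0.
    """
    out: dict[str, float | None] = {}
    pairs = {
        "accuracy": (c.TP + c.TN, c.total),
        "sensitivity": (c.TP, c.TP + c.FN),
        "precision": (c.TP, c.TP + c.FP),
        "specificity": (c.TN, c.FP + c.TN),
    }
    for name, (num, den) in pairs.items():
        if den == 0:
            warnings.warn(f"{name} undefined: zero denominator", stacklevel=2)
            out[name] = None
        else:
            out[name] = num / den
    return out


@dataclass
class CVPlan:
    """Fold assignments for repeated stratified k-fold CV."""

    k: int
    repeats: int
    seed: int
    assignments: list[np.ndarray]  # per repeat: fold index per sample

    def splits(self):
        """Yield (repeat, fold, train_idx, test_idx) over all k*repeats folds."""
        for r, folds in enumerate(self.assignments):
            for f in range(self.k):
                test = np.flatnonzero(folds == f)
                train = np.flatnonzero(folds != f)
                yield r, f, train, test

    def digest(self) -> str:
        h = hashlib.sha256()
        for a in self.assignments:
            h.update(a.astype(np.int64).tobytes())
        return h.hexdigest()[:16]


def make_cv_plan(labels, k: int = 5, repeats: int = 5, seed: int = 0) -> CVPlan:
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        raise ValueError(f"every class needs at least k={k} samples")
    assignments = []
    for r in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + r)
        folds = np.empty(len(labels), dtype=np.int64)
        for f, (_, test) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            folds[test] = f
        assignments.append(folds)
    return CVPlan(k=k, repeats=repeats, seed=seed, assignments=assignments)


@dataclass
class MetricsReport:
    per_fold: pd.DataFrame  # repeat, fold, TP, TN, FP, FN + metric columns
    plan_digest: str
    scaler_digests: tuple[str, ...] = ()

    @property
    def mean(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].mean()) for m in METRIC_NAMES}

    @property
    def std(self) -> dict[str, float]:
        return {m: float(self.per_fold[m].std(ddof=1)) for m in METRIC_NAMES}

    def summary(self) -> dict:
        return {
            "mean": self.mean,
            "std": self.std,
            "n_folds": int(len(self.per_fold)),
            "plan_digest": self.plan_digest,
        }


def _fold_frame(rows: list[dict], plan: CVPlan,
                scaler_digests=()) -> MetricsReport:
    return MetricsReport(pd.DataFrame(rows), plan.digest(),
                         tuple(scaler_digests))


def run_cv(
    block: FeatureBlock,
    labels,
    layout: GridLayout,
    config: ModelConfig,
    plan: CVPlan,
) -> MetricsReport:
    """Train/evaluate the model over every fold of the plan.

    The z-scorer is fit inside each training fold; each fold trains a fresh
    model seeded from ``config.seed`` plus the fold counter, so the whole
    report is deterministic given (block, labels, plan, config).
    """
    labels = np.asarray(labels, dtype=np.int64)
    rows, digests = [], []
    for r, f, train_idx, test_idx in plan.splits():
        train_block = FeatureBlock(block.values[train_idx], block.feature_names,
                                   block.channel_names)
        test_block = FeatureBlock(block.values[test_idx], block.feature_names,
                                  block.channel_names)
        stats = fit_scaler(train_block, layout)
        digests.append(stats.digest())
        x_train, y_train = stack_samples(
            assemble_tensor(train_block, layout, stats, labels[train_idx])
        )
        x_test, y_test = stack_samples(
            assemble_tensor(test_block, layout, stats, labels[test_idx])
        )
        fold_seed = config.seed + 1000 * r + f
        model = SeizurePredictor(dataclasses.replace(config, seed=fold_seed))
        model.fit(x_train, y_train)
        c = confusion_from_predictions(y_test, model.predict(x_test))
        row = {"repeat": r, "fold": f, "TP": c.TP, "TN": c.TN, "FP": c.FP,
               "FN": c.FN, **{k: v for k, v in metrics(c).items()}}
        rows.append(row)
        logger.info("repeat %d fold %d: acc=%.3f", r, f, row["accuracy"])
    return _fold_frame(rows, plan, digests)


def _run_sklearn_cv(clf_factory, features_1d, labels, plan: CVPlan) -> MetricsReport:
    x = np.asarray(features_1d, dtype=np.float64)
    y = np.asarray(labels, dtype=np.int64)
    if x.ndim != 2:
        raise ValueError("baseline features must be a 2-D (samples x dims) array")
    if len(y) != x.shape[0] or any(len(a) != len(y) for a in plan.assignments):
        raise ValueError("plan does not match the dataset size")
    rows = []
    for r, f, train_idx, test_idx in plan.splits():
        mu = x[train_idx].mean(axis=0)
        sd = x[train_idx].std(axis=0)
        sd[sd == 0] = 1.0
        clf = clf_factory()
        clf.fit((x[train_idx] - mu) / sd, y[train_idx])
        pred = clf.predict((x[test_idx] - mu) / sd)
        c = confusion_from_predictions(y[test_idx], pred)
        rows.append({"repeat": r, "fold": f, "TP": c.TP, "TN": c.TN,
                     "FP": c.FP, "FN": c.FN, **metrics(c)})
    return _fold_frame(rows, plan)


def baseline_knn(features_1d, labels, plan: CVPlan,
                 n_neighbors: int = 5) -> MetricsReport:
    """KNN (k=5, Minkowski p=2) on flattened step x feature x channel vectors."""
    return _run_sklearn_cv(
        lambda: KNeighborsClassifier(n_neighbors=n_neighbors, metric="minkowski"),
        features_1d, labels, plan,
    )


def baseline_svm(features_1d, labels, plan: CVPlan) -> MetricsReport:
    """SVM with RBF kernel, one-vs-one decision function, C=1, scaled gamma."""
    return _run_sklearn_cv(
        lambda: SVC(kernel="rbf", decision_function_shape="ovo", C=1.0,
                    gamma="scale"),
        features_1d, labels, plan,
    )


def flatten_features(block: FeatureBlock) -> np.ndarray:
    """(windows, steps*features*channels) 1-D vectors for the baselines."""
    w = block.values.shape[0]
    return block.values.reshape(w, -1)
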