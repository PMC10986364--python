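"""Minimum-redundancy maximum-relevance (mRMR) feature ranking and the
accuracy sweep that decides how many ranked variables to keep.

Relevance of a candidate is its mutual information with the class label;
redundancy is its mean mutual information with the already-selected set.
The incremental criterion for the next pick is

    score(x_j) = I(x_j; c) - (1/|S|) * sum_{x_i in S} I(x_i; x_j)

with the first pick being the max-relevance variable. Continuous variables
are discretized by equal-frequency binning before the plug-in MI estimate
(natural-log units).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import mutual_info_score

from .features import FeatureBlock

MAX_BINS = 16


@dataclass
class FeatureMatrix:
    """Samples x variables matrix with binary labels."""

    X: np.ndarray
    y: np.ndarray
    variable_names: tuple[str, ...]

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if len(self.y) != self.X.shape[0]:
            raise ValueError("label length mismatch")
        if self.X.shape[1] != len(self.variable_names):
            raise ValueError("variable name count mismatch")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("X contains missing or non-finite values")
        if len(np.unique(self.y)) < 2:
            raise ValueError("both classes must be present")


def build_feature_matrix(
    block: FeatureBlock, labels: np.ndarray, per_channel: bool = False
) -> FeatureMatrix:
    """Aggregate a FeatureBlock into ranking variables.

    Default: one variable per feature, averaged over channels and steps
    (four variables for the full feature set). ``per_channel=True`` keeps
    per-channel granularity with variables named ``feature:channel``.
    """
    if per_channel:
        x = block.values.mean(axis=1)  # (w, f, c)
        w, f, c = x.shape
        names = tuple(
            f"{fn}:{cn}" for fn in block.feature_names for cn in block.channel_names
        )
        return FeatureMatrix(x.reshape(w, f * c), labels, names)
    x = block.values.mean(axis=(1, 3))  # (w, f)
    return FeatureMatrix(x, labels, block.feature_names)


def _discretize(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a).ravel()
    bins = min(int(np.ceil(np.sqrt(a.size))), MAX_BINS)
    codes = np.unique(a, return_inverse=True)[1]
    if codes.max() + 1 <= bins:
        return codes  # already discrete enough: use values as categories
    edges = np.unique(np.quantile(a, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, a, side="right")


def mutual_information(a, b) -> float:
    """Plug-in mutual information (nats) between two series.

    Continuous inputs are equal-frequency binned into
    min(ceil(sqrt(n)), 16) bins; inputs with few distinct values are used
    as categories directly.
    """
    a, b = np.asarray(a).ravel(), np.asarray(b).ravel()
    if a.size != b.size:
        raise ValueError("series must have equal length")
    if a.size < 2:
        raise ValueError("series must have length >= 2")
    return float(mutual_info_score(_discretize(a), _discretize(b)))


@dataclass
class SelectionState:
    """Intermediate mRMR bookkeeping, exposed for the exhaustive oracle."""

    selected: list[str]
    remaining: list[str]
    relevance: dict[str, float]
    redundancy: dict[str, float]
    scores: dict[str, float]


@dataclass
class SelectionResult:
    ranked_names: tuple[str, ...]
    importance: tuple[float, ...]  # incremental score at selection time
    chosen_k: int | None = None
    history: list[SelectionState] = field(default_factory=list, repr=False)

    @property
    def importance_scaled(self) -> tuple[float, ...]:
        """Importance min-max rescaled to [0, 1] for display."""
        raw = np.asarray(self.importance)
        span = raw.max() - raw.min()
        if span == 0:
            return tuple(np.ones_like(raw))
        return tuple((raw - raw.min()) / span)

    def to_json(self, path=None, **extra) -> str:
        payload = {
            "ranked_names": list(self.ranked_names),
            "importance": list(self.importance),
            "importance_scaled": list(self.importance_scaled),
            "chosen_k": self.chosen_k,
            "mi_binning": {"rule": "equal-frequency", "max_bins": MAX_BINS},
            **extra,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text


def mrmr_rank(fm: FeatureMatrix) -> SelectionResult:
    """Full incremental mRMR ordering with per-step scores.

    Ties are broken by lexicographic variable-name order. A constant
    variable has zero relevance but remains rankable.
    """
    if fm.X.shape[1] == 0:
        raise ValueError("no candidate variables")
    cols = {n: fm.X[:, i] for i, n in enumerate(fm.variable_names)}
    relevance = {n: mutual_information(cols[n], fm.y) for n in fm.variable_names}
    # candidate order for tie-breaks
    names_sorted = sorted(fm.variable_names)
    pair_mi: dict[tuple[str, str], float] = {}

    def mi_pair(a: str, b: str) -> float:
        key = (a, b) if a <= b else (b, a)
        if key not in pair_mi:
            pair_mi[key] = mutual_information(cols[key[0]], cols[key[1]])
        return pair_mi[key]

    selected: list[str] = []
    importance: list[float] = []
    history: list[SelectionState] = []
    remaining = list(names_sorted)
    while remaining:
        redundancy = {
            n: (np.mean([mi_pair(n, s) for s in selected]) if selected else 0.0)
            for n in remaining
        }
        scores = {n: relevance[n] - redundancy[n] for n in remaining}
        history.append(SelectionState(list(selected), list(remaining),
                                      dict(relevance), redundancy, scores))
        # remaining is name-sorted and max() keeps the first of equal keys,
        # so ties break by variable-name order
        best = max(remaining, key=lambda n: scores[n])
        selected.append(best)
        importance.append(float(scores[best]))
        remaining.remove(best)
    return SelectionResult(tuple(selected), tuple(importance), history=history)


@dataclass
class SweepResult:
    chosen_k: int
    accuracies: tuple[float, ...]


def feature_count_sweep(
    fm: FeatureMatrix,
    ranked_names: tuple[str, ...],
    evaluator,
    k_max: int | None = None,
) -> SweepResult:
    """Accuracy with the top-j ranked variables for j = 1..k_max.

    ``evaluator(X_subset, y) -> accuracy`` runs a fixed, seeded CV plan.
    Returns the smallest j achieving the maximum accuracy.
    """
    if k_max is None:
        k_max = len(ranked_names)
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    if k_max > len(ranked_names):
        raise ValueError("k_max exceeds number of ranked variables")
    name_idx = {n: i for i, n in enumerate(fm.variable_names)}
    accs = []
    for j in range(1, k_max + 1):
        idx = [name_idx[n] for n in ranked_names[:j]]
        accs.append(float(evaluator(fm.X[:, idx], fm.y)))
    chosen = int(np.argmax(accs)) + 1  # argmax returns the first (smallest j) max
    return SweepResult(chosen_k=chosen, accuracies=tuple(accs))


def knn_cv_evaluator(n_neighbors: int = 5, n_splits: int = 5, seed: int = 0):
    """Default fast sweep evaluator: seeded stratified-CV KNN accuracy."""
    from sklearn.model_selection import StratifiedKFold, cross_val_score
    from sklearn.neighbors import KNeighborsClassifier

    def evaluate(X, y) -> float:
        cv = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
        clf = KNeighborsClassifier(n_neighbors=n_neighbors, metric="minkowski")
        return float(cross_val_score(clf, X, y, cv=cv).mean())

    return evaluate
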