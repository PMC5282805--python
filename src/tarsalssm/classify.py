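"""Four-class tarsal-bone recognition from SPHARM coefficient features.

A random-forest ensemble (scikit-learn) is evaluated by stratified k-fold
cross-validation with the confusion matrix pooled over folds — matching a
single printed misclassification rate rather than a per-fold average.  The
fold stratification, the tree-count sweep, and the one-vs-rest
sensitivity/specificity formulas are implemented here and oracle-tested; the
forest itself is the standard learner.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .errors import InvalidInputError, StratificationError

__all__ = [
    "FeatureMatrix",
    "ClassifierReport",
    "stratified_folds",
    "crossval_classify",
    "sweep_trees",
    "class_metrics",
]

DEFAULT_TREE_GRID = (10, 20, 40, 80, 160)


@dataclass
class FeatureMatrix:
    """Samples x SPHARM-coefficient feature matrix with class labels."""

    X: np.ndarray  # (n_samples, n_features)
    labels: np.ndarray  # class name per row
    sides: np.ndarray | None = None  # metadata only

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.X.ndim != 2 or len(self.X) != len(self.labels):
            raise InvalidInputError("X must be 2D with one label per row")
        if not np.all(np.isfinite(self.X)):
            raise InvalidInputError("feature matrix contains non-finite values")
        if len(np.unique(self.labels)) < 2:
            raise InvalidInputError("need at least two classes")
        if self.sides is not None and len(self.sides) != len(self.labels):
            raise InvalidInputError("sides metadata length mismatch")

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.X, columns=[f"k{j}" for j in range(self.X.shape[1])])
        df.insert(0, "label", self.labels)
        if self.sides is not None:
            df.insert(1, "side", self.sides)
        df.to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "FeatureMatrix":
        df = pd.read_csv(path)
        sides = df.pop("side").to_numpy() if "side" in df else None
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(dtype=float), labels, sides)


@dataclass
class ClassifierReport:
    """Cross-validated recognition report, confusion pooled over folds."""

    n_trees: int
    classes: list[str]
    confusion: np.ndarray  # rows = truth, cols = predicted
    misclassification_rate: float
    sensitivity: dict[str, float | None]
    specificity: dict[str, float | None]
    n_folds: int
    seed: int
    fold_sizes: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "n_trees": self.n_trees,
                    "classes": self.classes,
                    "confusion": self.confusion.tolist(),
                    "misclassification_rate": self.misclassification_rate,
                    "sensitivity": self.sensitivity,
                    "specificity": self.specificity,
                    "n_folds": self.n_folds,
                    "seed": self.seed,
                    "fold_sizes": self.fold_sizes,
                },
                sort_keys=True,
                indent=1,
            )
        )


def stratified_folds(labels: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Deterministic stratified fold assignment.

    Members of each class are shuffled with the seeded generator and dealt
    round-robin to folds, so every fold holds each class in near-equal
    proportion.  Raises :class:`StratificationError` when any class has
    fewer members than folds.
    """
    labels = np.asarray(labels)
    if n_folds < 2:
        raise InvalidInputError("n_folds must be >= 2")
    rng = np.random.default_rng(seed)
    folds = np.full(len(labels), -1, dtype=int)
    offset = 0
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < n_folds:
            raise StratificationError(
                f"class {cls!r} has {len(members)} members < {n_folds} folds"
            )
        members = rng.permutation(members)
        # rotate the starting fold per class so small remainders spread out
        folds[members] = (np.arange(len(members)) + offset) % n_folds
        offset += len(members)
    return folds


def _pooled_confusion(
    fm: FeatureMatrix, folds: np.ndarray, n_trees: int, seed: int
) -> np.ndarray:
    classes = list(fm.classes)
    cls_index = {c: i for i, c in enumerate(classes)}
    conf = np.zeros((len(classes), len(classes)), dtype=int)
    for f in range(folds.max() + 1):
        test = folds == f
        clf = RandomForestClassifier(
            n_estimators=n_trees, random_state=int((seed * 1009 + f) % (2**31 - 1))
        )
        clf.fit(fm.X[~test], fm.labels[~test])
        pred = clf.predict(fm.X[test])
        for t, p in zip(fm.labels[test], pred):
            conf[cls_index[t], cls_index[p]] += 1
    return conf


def crossval_classify(
    fm: FeatureMatrix, n_trees: int = 40, n_folds: int = 10, seed: int = 0,
    folds: np.ndarray | None = None,
) -> ClassifierReport:
    """Stratified k-fold cross-validated random-forest recognition.

    The confusion matrix is pooled over held-out predictions of all folds;
    the misclassification rate is its off-diagonal fraction.  Identical
    inputs and seed produce an identical report.  A precomputed ``folds``
    assignment may be shared across calls (used by the tree sweep).
    """
    if folds is None:
        folds = stratified_folds(fm.labels, n_folds, seed)
    conf = _pooled_confusion(fm, folds, n_trees, seed)
    sens, spec = class_metrics(conf)
    classes = list(fm.classes)
    total = conf.sum()
    return ClassifierReport(
        n_trees=n_trees,
        classes=[str(c) for c in classes],
        confusion=conf,
        misclassification_rate=float((total - np.trace(conf)) / total),
        sensitivity={str(c): sens[i] for i, c in enumerate(classes)},
        specificity={str(c): spec[i] for i, c in enumerate(classes)},
        n_folds=int(folds.max() + 1),
        seed=seed,
        fold_sizes=[int(np.sum(folds == f)) for f in range(folds.max() + 1)],
    )


def sweep_trees(
    fm: FeatureMatrix,
    tree_grid: tuple[int, ...] = DEFAULT_TREE_GRID,
    n_folds: int = 10,
    seed: int = 0,
) -> tuple[int, dict[int, float]]:
    """Misclassification rate per ensemble size over a shared fold split.

    Returns (best tree count, {count: rate}); ties resolve to the smaller
    count.
    """
    if not tree_grid:
        raise InvalidInputError("tree_grid must be non-empty")
    folds = stratified_folds(fm.labels, n_folds, seed)
    rates: dict[int, float] = {}
    for n in sorted(tree_grid):
        rates[int(n)] = crossval_classify(fm, n, n_folds, seed, folds=folds).misclassification_rate
    best = min(rates, key=lambda n: (rates[n], n))
    return best, rates


def class_metrics(
    confusion: np.ndarray,
) -> tuple[list[float | None], list[float | None]]:
    """One-vs-rest sensitivity TP/(TP+FN) and specificity TN/(TN+FP) per
    class from a pooled confusion matrix (rows = truth, cols = predicted).

    Division-by-zero cells yield ``None`` (undefined), never 0.
    """
    conf = np.asarray(confusion)
    if conf.ndim != 2 or conf.shape[0] != conf.shape[1]:
        raise InvalidInputError("confusion matrix must be square")
    if np.any(conf < 0) or not np.issubdtype(conf.dtype, np.integer):
        raise InvalidInputError("confusion matrix must hold nonnegative integers")
    total = conf.sum()
    if total == 0:
        raise InvalidInputError("all-zero confusion matrix: nothing to report")
    sens: list[float | None] = []
    spec: list[float | None] = []
    for i in range(conf.shape[0]):
        tp = conf[i, i]
        fn = conf[i].sum() - tp
        fp = conf[:, i].sum() - tp
        tn = total - tp - fn - fp
        sens.append(float(tp / (tp + fn)) if tp + fn > 0 else None)
        spec.append(float(tn / (tn + fp)) if tn + fp > 0 else None)
    return sens, spec
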