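"""Random-Forest classification of PC scores.

Covers the train/test split, cross-validated accuracy, hold-out confusion
matrix and per-class metrics, impurity-based per-PC importances, and a
Boruta-style shadow-feature relevance screen.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix, precision_recall_fscore_support
from sklearn.model_selection import KFold, StratifiedKFold, train_test_split


@dataclass(frozen=True)
class ClassifierConfig:
    n_trees: int = 50
    train_fraction: float = 0.70
    k_folds: int = 10
    n_pcs: int = 25
    pc_indices: tuple[int, ...] | None = None  # explicit 1-based list, e.g. 2..20
    boruta_iterations: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.k_folds < 2 or self.n_trees < 1:
            raise ValueError("k_folds must be >= 2 and n_trees >= 1")

    def selected_indices(self) -> tuple[int, ...]:
        if self.pc_indices is not None:
            return tuple(self.pc_indices)
        return tuple(range(1, self.n_pcs + 1))


@dataclass
class ClassificationReport:
    """Everything the classifier stage reports about one experiment."""

    fold_accuracies: np.ndarray
    confusion: pd.DataFrame = field(repr=False)  # rows true, columns predicted
    per_class: pd.DataFrame = field(repr=False)  # precision/recall/F1/support
    importances: np.ndarray  # per selected PC, sums to 1
    pc_indices: tuple[int, ...]
    boruta_decision: dict[int, str] | None = None

    @property
    def accuracy_mean(self) -> float:
        return float(np.mean(self.fold_accuracies))

    @property
    def accuracy_sd(self) -> float:
        return float(np.std(self.fold_accuracies, ddof=1))

    @property
    def holdout_accuracy(self) -> float:
        c = self.confusion.to_numpy()
        return float(np.trace(c) / c.sum())

    def to_dict(self) -> dict:
        return {
            "fold_accuracies": [float(a) for a in self.fold_accuracies],
            "accuracy_mean": self.accuracy_mean,
            "accuracy_sd": self.accuracy_sd,
            "holdout_accuracy": self.holdout_accuracy,
            "confusion": {
                "classes": [str(c) for c in self.confusion.index],
                "counts": self.confusion.to_numpy().tolist(),
            },
            "per_class": self.per_class.to_dict(orient="index"),
            "pc_indices": list(self.pc_indices),
            "importances": [float(v) for v in self.importances],
            "boruta_decision": (
                {str(k): v for k, v in self.boruta_decision.items()}
                if self.boruta_decision is not None
                else None
            ),
        }


def split_train_test(
    scores: np.ndarray,
    labels: np.ndarray,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[tuple[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]]:
    """Stratified, reproducible train/test split of score rows."""
    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    if counts.min() < 2:
        raise ValueError("every class needs at least 2 rows to stratify")
    X_tr, X_te, y_tr, y_te = train_test_split(
        scores,
        labels,
        train_size=train_fraction,
        stratify=labels,
        random_state=seed,
    )
    return (X_tr, y_tr), (X_te, y_te)


def train_rf(
    scores: np.ndarray, labels: np.ndarray, n_trees: int = 50, seed: int = 0
) -> RandomForestClassifier:
    """Fit the 50-tree (by default) forest; deterministic given the seed."""
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValueError("need at least 2 classes to train")
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(scores, labels)
    return forest


def cross_validate(
    scores: np.ndarray,
    labels: np.ndarray,
    k: int = 10,
    n_trees: int = 50,
    seed: int = 0,
) -> np.ndarray:
    """Stratified k-fold cross-validation; returns the k fold accuracies."""
    labels = np.asarray(labels)
    n = labels.size
    if k > n:
        raise ValueError("k cannot exceed the number of rows")
    _, counts = np.unique(labels, return_counts=True)
    if counts.min() < k:
        warnings.warn(
            "some class has fewer rows than folds; stratification is relaxed",
            stacklevel=2,
        )
        kf = KFold(n_splits=k, shuffle=True, random_state=seed)
    else:
        kf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    accs = []
    for fold, (tr, te) in enumerate(kf.split(scores, labels)):
        forest = train_rf(scores[tr], labels[tr], n_trees=n_trees, seed=seed + fold)
        accs.append(float(np.mean(forest.predict(scores[te]) == labels[te])))
    return np.asarray(accs)


def evaluate(
    forest: RandomForestClassifier,
    test_scores: np.ndarray,
    test_labels: np.ndarray,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Confusion matrix (rows true, columns predicted) and per-class metrics.

    Test labels unseen during training keep their own confusion row; the
    forest can never predict them, so they count as errors.
    """
    test_labels = np.asarray(test_labels)
    pred = forest.predict(test_scores)
    classes = np.unique(np.concatenate([forest.classes_, test_labels]))
    counts = confusion_matrix(test_labels, pred, labels=classes)
    confusion = pd.DataFrame(counts, index=classes, columns=classes)
    precision, recall, f1, support = precision_recall_fscore_support(
        test_labels, pred, labels=classes, zero_division=0
    )
    per_class = pd.DataFrame(
        {
            "precision": precision,
            "recall": recall,
            "f1": f1,
            "support": support,
        },
        index=classes,
    )
    return confusion, per_class


def feature_importance(forest: RandomForestClassifier) -> np.ndarray:
    """Mean impurity-decrease importance per feature, normalized to sum 1."""
    imp = forest.feature_importances_.astype(float)
    total = imp.sum()
    return imp / total if total > 0 else imp


def boruta_select(
    scores: np.ndarray,
    labels: np.ndarray,
    iterations: int = 10,
    n_trees: int = 50,
    seed: int = 0,
    alpha: float = 0.05,
) -> list[str]:
    """Shadow-feature relevance screen over repeated forest fits.

    Each iteration appends a column-permuted ("shadow") copy of every
    feature, fits the forest, and scores a *hit* for each real feature whose
    importance beats the best shadow importance.  Hits follow Binomial(n,
    1/2) for an irrelevant feature, so a one-sided binomial test at ``alpha``
    declares each feature confirmed (significantly many hits), rejected
    (significantly few) or tentative.
    """
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    X = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    n, p = X.shape
    hits = np.zeros(p, dtype=int)
    for it in range(iterations):
        shadow = X.copy()
        for j in range(p):
            rng.shuffle(shadow[:, j])
        forest = RandomForestClassifier(
            n_estimators=n_trees, random_state=seed * 1000 + it
        )
        forest.fit(np.hstack([X, shadow]), y)
        imp = forest.feature_importances_
        hits += imp[:p] > imp[p:].max()
    decisions = []
    for h in hits:
        if binom.sf(h - 1, iterations, 0.5) < alpha:
            decisions.append("confirmed")
        elif binom.cdf(h, iterations, 0.5) < alpha:
            decisions.append("rejected")
        else:
            decisions.append("tentative")
    return decisions
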