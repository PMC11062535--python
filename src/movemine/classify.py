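"""Positional-group classification on binary pattern-presence features.

Each player-match observation becomes a row of 0/1 indicators — did this
player perform this unique pattern in this fixture (i.e. was it in the
set mined from that corpus)? — labelled by playing position. Five
off-the-shelf classifiers are compared under shuffled (unstratified)
10-fold cross-validation, and the L1 logistic model's coefficient
magnitudes rank the most discriminative patterns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import accuracy_score, precision_recall_fscore_support
from sklearn.model_selection import KFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier

from .mining import Pattern, PatternSet, UniquePatternSet

DEFAULT_FOLDS = 10
DEFAULT_SHUFFLE_SEED = 10

#: The five classifier settings: defaults except for the seeds, the L1
#: penalty of the logistic model and the MLP iteration cap.
CLASSIFIER_FACTORIES = {
    "DecisionTree": lambda: DecisionTreeClassifier(),
    "GaussianNaiveBayes": lambda: GaussianNB(),
    "RandomForest": lambda: RandomForestClassifier(random_state=1),
    # L1 penalty, liblinear solver (l1_ratio=1 is the current spelling of
    # penalty="l1")
    "LogisticRegression": lambda: LogisticRegression(l1_ratio=1.0, solver="liblinear"),
    "MLP": lambda: MLPClassifier(max_iter=300, random_state=5),
}
CLASSIFIER_NAMES = tuple(CLASSIFIER_FACTORIES)


def make_classifier(name: str):
    try:
        return CLASSIFIER_FACTORIES[name]()
    except KeyError:
        raise ValueError(
            f"unknown classifier {name!r}; choose from {CLASSIFIER_NAMES}"
        ) from None


class PatternPresenceEncoder(BaseEstimator, TransformerMixin):
    """sklearn transformer: list of per-corpus ``PatternSet`` -> binary
    presence matrix over the fitted union vocabulary.

    ``fit`` learns the vocabulary (the sorted unique union of the given
    sets); ``transform`` marks 1 where a vocabulary pattern was extracted
    from the observation's corpus.
    """

    def __init__(self, vocabulary: Sequence[Pattern] | None = None):
        self.vocabulary = vocabulary

    def fit(self, X: Sequence[PatternSet], y=None):
        if self.vocabulary is not None:
            vocab = list(self.vocabulary)
        else:
            vocab = sorted({sp.pattern for ps in X for sp in ps.patterns})
        self.vocabulary_ = vocab
        self._index_ = {p: i for i, p in enumerate(vocab)}
        return self

    def transform(self, X: Sequence[PatternSet]) -> np.ndarray:
        out = np.zeros((len(X), len(self.vocabulary_)), dtype=np.int8)
        for r, ps in enumerate(X):
            for sp in ps.patterns:
                j = self._index_.get(sp.pattern)
                if j is not None:
                    out[r, j] = 1
        return out


def build_feature_matrix(per_corpus_sets: Sequence[PatternSet],
                         union: UniquePatternSet) -> pd.DataFrame:
    """Observations x unique-patterns binary table with a ``label`` column.

    Rows follow ``per_corpus_sets`` order (one player-match each); columns
    are the union's patterns in sorted order, named by their items; the
    label is the corpus position.
    """
    for ps in per_corpus_sets:
        if ps.algorithm != union.algorithm:
            raise ValueError(
                f"pattern set tagged {ps.algorithm!r} does not match the "
                f"{union.algorithm!r} union"
            )
    vocab = sorted(union.pattern_keys())
    enc = PatternPresenceEncoder(vocabulary=vocab).fit(per_corpus_sets)
    X = enc.transform(per_corpus_sets)
    df = pd.DataFrame(X, columns=[p.items for p in vocab])
    df["label"] = [ps.position for ps in per_corpus_sets]
    return df


@dataclass
class CvResult:
    """Per-fold and aggregated metrics of one classifier on one dataset."""

    classifier: str
    algorithm: str
    fold_accuracy: list[float] = field(default_factory=list)
    fold_precision: list[float] = field(default_factory=list)
    fold_recall: list[float] = field(default_factory=list)
    fold_f1: list[float] = field(default_factory=list)

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def precision(self) -> float:
        return float(np.mean(self.fold_precision))

    @property
    def recall(self) -> float:
        return float(np.mean(self.fold_recall))

    @property
    def f1(self) -> float:
        return float(np.mean(self.fold_f1))

    def summary(self) -> dict:
        return {
            "classifier": self.classifier,
            "algorithm": self.algorithm,
            "accuracy": self.accuracy,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
        }


def run_cv(matrix: pd.DataFrame,
           classifiers: Sequence[str] = CLASSIFIER_NAMES,
           folds: int = DEFAULT_FOLDS,
           shuffle_seed: int = DEFAULT_SHUFFLE_SEED,
           average: str = "weighted",
           algorithm: str = "") -> list[CvResult]:
    """Shuffled (unstratified) k-fold cross-validation of the named
    classifiers on a feature matrix with a ``label`` column.

    Precision/recall/F1 are averaged over the two classes by ``average``
    ("weighted" by class support, or "macro"); aggregates are the plain
    means over folds.
    """
    if "label" not in matrix.columns:
        raise ValueError("feature matrix must carry a 'label' column")
    y = matrix["label"].to_numpy()
    X = matrix.drop(columns="label").to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("cross-validation needs both class labels present")
    if len(y) < folds:
        raise ValueError(f"{len(y)} rows cannot be split into {folds} folds")
    if average not in ("weighted", "macro"):
        raise ValueError("average must be 'weighted' or 'macro'")
    kf = KFold(n_splits=folds, shuffle=True, random_state=shuffle_seed)
    splits = list(kf.split(X))
    results = []
    for name in classifiers:
        res = CvResult(classifier=name, algorithm=algorithm)
        for train, test in splits:
            model = make_classifier(name)
            model.fit(X[train], y[train])
            pred = model.predict(X[test])
            res.fold_accuracy.append(accuracy_score(y[test], pred))
            p, r, f, _ = precision_recall_fscore_support(
                y[test], pred, average=average, zero_division=0
            )
            res.fold_precision.append(p)
            res.fold_recall.append(r)
            res.fold_f1.append(f)
        results.append(res)
    return results


@dataclass
class ImportanceRanking:
    """Top patterns ranked by non-negative importance score."""

    entries: list[tuple[str, float, int]]  # (pattern items, score, rank)

    def __iter__(self):
        return iter(self.entries)

    def __len__(self):
        return len(self.entries)


def rank_importance(coefficients: Sequence[float],
                    pattern_names: Sequence[str],
                    top_n: int = 20) -> ImportanceRanking:
    """Rank patterns by absolute coefficient, descending; ties break
    lexicographically; truncated to ``top_n``."""
    coefficients = np.asarray(coefficients, dtype=float).ravel()
    if len(coefficients) != len(pattern_names):
        raise ValueError(
            f"{len(coefficients)} coefficients for {len(pattern_names)} patterns"
        )
    order = sorted(
        range(len(pattern_names)),
        key=lambda i: (-abs(coefficients[i]), pattern_names[i]),
    )[:top_n]
    return ImportanceRanking(
        [(pattern_names[i], float(abs(coefficients[i])), r + 1)
         for r, i in enumerate(order)]
    )


def logistic_importance(matrix: pd.DataFrame, top_n: int = 20) -> ImportanceRanking:
    """Fit the L1 logistic model on the full matrix and rank its top
    ``top_n`` patterns by coefficient magnitude."""
    y = matrix["label"].to_numpy()
    X = matrix.drop(columns="label")
    model = make_classifier("LogisticRegression").fit(X.to_numpy(dtype=float), y)
    return rank_importance(model.coef_.ravel(), list(X.columns), top_n)
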