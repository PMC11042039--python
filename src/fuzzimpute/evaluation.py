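"""Classification-accuracy benchmark harness.

The evaluation protocol mirrors the standard downstream assessment of an
imputer: impute the full table, split into stratified train/test sets,
min-max normalize with parameters fitted on the training split only,
fit a classifier, and score accuracy = (TP + TN) / (TP + TN + FP + FN)
x 100 from the confusion matrix on the held-out split.

Four classifiers are swept (scikit-learn implementations): k-nearest
neighbors with the Euclidean metric, Gaussian naive Bayes, a decision
tree, and a multi-layer perceptron.  The fuzzy imputers are additionally
swept over k in {3, 5, 7, 9}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.tree import DecisionTreeClassifier

from .baselines import listwise_delete, mean_impute, median_impute
from .imputation import ImputerConfig, impute_matrix
from .matrix import FeatureMatrix

__all__ = [
    "ConfusionMatrix",
    "BenchmarkResult",
    "SplitSpec",
    "CLASSIFIERS",
    "FUZZY_IMPUTERS",
    "BASELINE_IMPUTERS",
    "DEFAULT_K_GRID",
    "accuracy",
    "min_max_normalize",
    "run_benchmark",
    "summarize",
]

CLASSIFIERS = ("knn", "naive_bayes", "decision_tree", "neural_network")
FUZZY_IMPUTERS = ("triangular", "gaussian")
BASELINE_IMPUTERS = ("mean", "median", "listwise", "none")
DEFAULT_K_GRID = (3, 5, 7, 9)


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class BenchmarkResult:
    """Accuracy of one (dataset, imputer, k, classifier) cell.

    ``accuracy`` is a percentage in [0, 100], or None when the cell
    failed (``error`` then carries the reason).
    """

    dataset: str
    imputer: str
    k: int | None
    classifier: str
    accuracy: float | None
    error: str | None = None


@dataclass(frozen=True)
class SplitSpec:
    """Train/test split settings: stratified 80/20 by default."""

    test_size: float = 0.2
    stratify: bool = True


def accuracy(cm: ConfusionMatrix) -> float:
    """(TP + TN) / (TP + TN + FP + FN) x 100."""
    if cm.total == 0:
        raise ValueError("confusion matrix is empty")
    return 100.0 * (cm.tp + cm.tn) / cm.total


def _accuracy_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    classes = np.unique(y_true)
    if classes.size == 2:
        pos = classes.max()
        cm = ConfusionMatrix(
            tp=int(((y_true == pos) & (y_pred == pos)).sum()),
            tn=int(((y_true != pos) & (y_pred != pos)).sum()),
            fp=int(((y_true != pos) & (y_pred == pos)).sum()),
            fn=int(((y_true == pos) & (y_pred != pos)).sum()),
        )
        return accuracy(cm)
    return 100.0 * float((y_true == y_pred).mean())


def min_max_normalize(
    train: FeatureMatrix, test: FeatureMatrix
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Rescale each feature by the training split's min and range.

    Test values are transformed with the train parameters and not
    clipped, so they may fall outside [0, 1].  A constant train column
    maps to 0 everywhere.
    """
    if train.feature_columns != test.feature_columns:
        raise ValueError("train and test must share feature columns")
    tr = train.data.copy()
    te = test.data.copy()
    for col in train.feature_columns:
        lo = float(tr[col].min())
        rng = float(tr[col].max()) - lo
        if rng == 0:
            tr[col] = 0.0
            te[col] = 0.0
        else:
            tr[col] = (tr[col] - lo) / rng
            te[col] = (te[col] - lo) / rng
    return FeatureMatrix(tr, train.label_column), FeatureMatrix(te, test.label_column)


def _make_classifier(name: str, seed: int):
    if name == "knn":
        return KNeighborsClassifier(metric="euclidean")
    if name == "naive_bayes":
        return GaussianNB()
    if name == "decision_tree":
        return DecisionTreeClassifier(random_state=seed)
    if name == "neural_network":
        return MLPClassifier(random_state=seed, max_iter=500)
    raise ValueError(f"unknown classifier {name!r}")


def _apply_imputer(dataset: FeatureMatrix, imputer: str, k: int | None) -> FeatureMatrix:
    if imputer in FUZZY_IMPUTERS:
        return impute_matrix(dataset, ImputerConfig(k=k or 3, membership=imputer))
    if imputer == "mean":
        return mean_impute(dataset)
    if imputer == "median":
        return median_impute(dataset)
    if imputer == "listwise":
        return listwise_delete(dataset)
    if imputer == "none":
        if not dataset.is_complete():
            raise ValueError("'none' imputer requires complete data")
        return dataset
    raise ValueError(f"unknown imputer {imputer!r}")


def _score_cell(
    complete: FeatureMatrix, classifier: str, split: SplitSpec, seed: int
) -> float:
    y = np.asarray(complete.labels())
    x = complete.feature_values()
    strat = y if split.stratify else None
    x_tr, x_te, y_tr, y_te = train_test_split(
        x, y, test_size=split.test_size, random_state=seed, stratify=strat
    )
    cols = complete.feature_columns
    tr = FeatureMatrix(pd.DataFrame(x_tr, columns=cols))
    te = FeatureMatrix(pd.DataFrame(x_te, columns=cols))
    tr, te = min_max_normalize(tr, te)
    model = _make_classifier(classifier, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(tr.feature_values(), y_tr)
        y_pred = model.predict(te.feature_values())
    return _accuracy_from_predictions(y_te, y_pred)


def run_benchmark(
    dataset: FeatureMatrix,
    imputers: Sequence[str] = FUZZY_IMPUTERS + BASELINE_IMPUTERS,
    k_grid: Sequence[int] = DEFAULT_K_GRID,
    classifiers: Sequence[str] = CLASSIFIERS,
    split_spec: SplitSpec | None = None,
    seed: int = 0,
    dataset_id: str = "dataset",
) -> list[BenchmarkResult]:
    """Sweep (imputer, k, classifier) cells on one labelled dataset.

    Fuzzy imputers are crossed with ``k_grid``; baselines run once each.
    A failing cell (for example listwise deletion emptying a class) is
    reported with ``error`` set, and the run continues.  Identical seeds
    reproduce identical results.
    """
    if dataset.label_column is None:
        raise ValueError("benchmark requires a label column")
    split = split_spec or SplitSpec()
    grid: list[tuple[str, int | None]] = [
        (imp, k) for imp in imputers if imp in FUZZY_IMPUTERS for k in k_grid
    ] + [(imp, None) for imp in imputers if imp not in FUZZY_IMPUTERS]
    results: list[BenchmarkResult] = []
    for imputer, k in grid:
        try:
            complete = _apply_imputer(dataset, imputer, k)
        except ValueError as exc:
            results.extend(
                BenchmarkResult(dataset_id, imputer, k, clf, None, str(exc))
                for clf in classifiers
            )
            continue
        for clf in classifiers:
            try:
                acc = _score_cell(complete, clf, split, seed)
                results.append(BenchmarkResult(dataset_id, imputer, k, clf, acc))
            except ValueError as exc:
                results.append(BenchmarkResult(dataset_id, imputer, k, clf, None, str(exc)))
    return results


def summarize(results: Iterable[BenchmarkResult]) -> pd.DataFrame:
    """Mean accuracy per (imputer, k, classifier) across datasets, ranked.

    Failed cells are excluded from the averages; the ``n_datasets``
    column reports how many datasets contributed to each mean.
    """
    rows = [r for r in results]
    if not rows:
        raise ValueError("no results to summarize")
    df = pd.DataFrame(
        {
            "dataset": [r.dataset for r in rows],
            "imputer": [r.imputer for r in rows],
            "k": [r.k if r.k is not None else -1 for r in rows],
            "classifier": [r.classifier for r in rows],
            "accuracy": [r.accuracy for r in rows],
        }
    )
    df = df.dropna(subset=["accuracy"])
    if df.empty:
        raise ValueError("all benchmark cells failed")
    out = (
        df.groupby(["imputer", "k", "classifier"], as_index=False)
        .agg(mean_accuracy=("accuracy", "mean"), n_datasets=("dataset", "nunique"))
        .sort_values("mean_accuracy", ascending=False, kind="stable")
        .reset_index(drop=True)
    )
    out["k"] = out["k"].where(out["k"] >= 0, other=pd.NA)
    return out
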