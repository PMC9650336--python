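"""Connectivity-feature classification: Gini ranking + top-n SVM.

Each 1-s analysis block is divided into 400-ms sliding windows with 50 %
overlap (four windows per block); each window's band PLV matrix, vectorised
over the strict upper triangle, is one sample.  A random forest fitted on the
training split ranks features by Gini (impurity) importance; SVMs on the top
5/10/15/20/25/30 features are then scored by 10-fold cross-validation on the
training split and by accuracy/AUC/ROC on the held-out 20 % test split.

All fitting artefacts -- the ranking, the standardisation statistics, the CV
folds -- are computed strictly inside the training split.  The default split
is stratified at the sample (window) level; a group-aware split that keeps
all windows of one epoch on the same side is available because windows cut
from the same block are strongly correlated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import accuracy_score, roc_curve, auc as _auc
from sklearn.model_selection import (GroupShuffleSplit, StratifiedKFold,
                                     cross_val_score, train_test_split)
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigurationError, ParameterError
from .connectivity import ConnectivityMatrix
from .preprocess import EEGEpoch

__all__ = [
    "DEFAULT_TOP_N",
    "FeatureSet",
    "FeatureRanking",
    "ClassifierReport",
    "window_bounds",
    "sliding_windows",
    "vectorize_features",
    "gini_rank",
    "evaluate_topn",
    "train_and_evaluate",
]

DEFAULT_TOP_N: tuple[int, ...] = (5, 10, 15, 20, 25, 30)


@dataclass
class FeatureSet:
    """Samples x features PLV design matrix with labels and grouping ids.

    ``feature_ids`` are (node_i, node_j, band_name) triples, one per strict
    upper-triangle entry in row-major node order; ``groups`` carries the
    source epoch of every sample so group-aware splits can avoid splitting an
    epoch's windows across train and test.
    """

    X: np.ndarray
    y: np.ndarray
    feature_ids: list[tuple[str, str, str]]
    groups: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y)
        self.groups = np.asarray(self.groups)
        if self.X.ndim != 2:
            raise ParameterError("X must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ParameterError("feature matrix contains non-finite values")
        if self.X.shape[0] != self.y.size or self.y.size != self.groups.size:
            raise ParameterError("X, y and groups must agree in sample count")
        if self.X.shape[1] != len(self.feature_ids):
            raise ParameterError("feature_ids must match the number of columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ParameterError("feature_ids must be unique")


@dataclass
class FeatureRanking:
    """Features ordered by descending Gini importance (ties broken by column index)."""

    order: np.ndarray
    gini: np.ndarray
    feature_ids: list[tuple[str, str, str]]

    def top(self, n: int) -> np.ndarray:
        if n > self.order.size:
            raise ParameterError(f"requested top {n} of {self.order.size} features")
        return self.order[:n]

    def top_ids(self, n: int) -> list[tuple[str, str, str]]:
        return [self.feature_ids[k] for k in self.top(n)]


@dataclass
class ClassifierReport:
    """Per-n SVM performance plus split/CV metadata."""

    results: dict[int, dict]
    seed: int
    kernel: str
    n_train: int
    n_test: int
    cv_folds: int
    group_split: bool


def window_bounds(n_samples: int, fs: float, win: float = 0.4,
                  overlap: float = 0.5) -> list[tuple[int, int]]:
    """(start, stop) sample bounds of sliding windows, half-open intervals.

    Window length is floor(fs * win) samples and the step is win * (1 -
    overlap): a 1-s block at 400 ms / 50 % yields exactly the four windows
    starting at 0, 0.2, 0.4 and 0.6 s.
    """
    if not (0 <= overlap < 1):
        raise ParameterError("overlap must lie in [0, 1)")
    n_win = int(np.floor(fs * win))
    if n_win < 2 or n_win > n_samples:
        raise ParameterError(f"window ({n_win} samples) must fit inside the block ({n_samples})")
    step = max(1, int(round(n_win * (1.0 - overlap))))
    bounds = []
    start = 0
    while start + n_win <= n_samples:
        bounds.append((start, start + n_win))
        start += step
    return bounds


def sliding_windows(block: EEGEpoch, win: float = 0.4, overlap: float = 0.5) -> list[EEGEpoch]:
    """Cut a block into sliding windows (as epochs with updated ``t0``)."""
    out = []
    for start, stop in window_bounds(block.n_samples, block.fs, win, overlap):
        out.append(EEGEpoch(data=block.data[:, start:stop], fs=block.fs,
                            channel_ids=block.channel_ids,
                            t0=block.t0 + start / block.fs))
    return out


def vectorize_features(conns: list[ConnectivityMatrix], y, groups) -> FeatureSet:
    """Stack PLV matrices into a samples x features matrix.

    Columns are the strict upper triangle in row-major node order, i.e. for
    4 nodes the pairs (1,2),(1,3),(1,4),(2,3),(2,4),(3,4).
    """
    if not conns:
        raise ParameterError("need at least one connectivity matrix")
    node_ids = conns[0].node_ids
    band_name = conns[0].band.name
    for c in conns:
        if c.node_ids != node_ids:
            raise ConfigurationError("node ordering differs between connectivity matrices")
    iu = np.triu_indices(len(node_ids), k=1)
    X = np.stack([c.values[iu] for c in conns])
    feature_ids = [(node_ids[i], node_ids[j], band_name) for i, j in zip(*iu)]
    return FeatureSet(X=X, y=np.asarray(y), feature_ids=feature_ids,
                      groups=np.asarray(groups))


def matrix_from_vector(vec: np.ndarray, n_nodes: int) -> np.ndarray:
    """Rebuild the symmetric matrix (unit diagonal) from an upper-triangle vector."""
    out = np.eye(n_nodes)
    iu = np.triu_indices(n_nodes, k=1)
    out[iu] = vec
    out.T[iu] = vec
    return out


def _check_two_classes(y: np.ndarray) -> None:
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2 or counts.min() < 2:
        raise ParameterError("need at least 2 samples of each of 2 classes")


def gini_rank(fs: FeatureSet, n_trees: int = 500, seed: int = 0,
              sample_idx: np.ndarray | None = None) -> FeatureRanking:
    """Rank features by random-forest Gini importance.

    ``sample_idx`` restricts fitting to the training partition; importances
    are sklearn's normalised mean impurity decrease (they sum to 1 whenever
    any split occurred).  Ties are broken by feature index so the ranking is
    deterministic given the seed.
    """
    X = fs.X if sample_idx is None else fs.X[sample_idx]
    y = fs.y if sample_idx is None else fs.y[sample_idx]
    _check_two_classes(y)
    forest = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    forest.fit(X, y)
    gini = forest.feature_importances_
    order = np.lexsort((np.arange(gini.size), -gini))
    return FeatureRanking(order=order, gini=gini, feature_ids=fs.feature_ids)


def _split(fs: FeatureSet, seed: int, test_size: float, group_split: bool):
    idx = np.arange(fs.X.shape[0])
    if group_split:
        gss = GroupShuffleSplit(n_splits=1, test_size=test_size, random_state=seed)
        train, test = next(gss.split(idx, fs.y, fs.groups))
        return idx[train], idx[test]
    return train_test_split(idx, test_size=test_size, random_state=seed, stratify=fs.y)


def evaluate_topn(fs: FeatureSet, ranking: FeatureRanking,
                  n_list=DEFAULT_TOP_N, seed: int = 0, kernel: str = "rbf",
                  train_idx: np.ndarray | None = None,
                  test_idx: np.ndarray | None = None,
                  cv_folds: int = 10, test_size: float = 0.2,
                  group_split: bool = False) -> ClassifierReport:
    """Score SVMs on the top-n feature subsets.

    The ranking must come from the training split (see
    :func:`train_and_evaluate` for the leak-free end-to-end protocol).  Per n:
    features are standardised on training statistics, an SVM is fitted on the
    training split, 10-fold stratified CV accuracy is computed inside the
    training split, and accuracy / AUC / ROC are reported on the test split,
    with ME as the positive class.
    """
    if (train_idx is None) != (test_idx is None):
        raise ParameterError("provide both train_idx and test_idx or neither")
    if train_idx is None:
        train_idx, test_idx = _split(fs, seed, test_size, group_split)
    y_bin = (fs.y == "ME").astype(int) if fs.y.dtype.kind in "UOS" else fs.y.astype(int)
    results: dict[int, dict] = {}
    for n in n_list:
        cols = ranking.top(int(n))
        Xtr, ytr = fs.X[np.ix_(train_idx, cols)], y_bin[train_idx]
        Xte, yte = fs.X[np.ix_(test_idx, cols)], y_bin[test_idx]
        model = make_pipeline(StandardScaler(), SVC(kernel=kernel))
        cv = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
        cv_acc = cross_val_score(model, Xtr, ytr, cv=cv, scoring="accuracy")
        model.fit(Xtr, ytr)
        scores = model.decision_function(Xte)
        fpr, tpr, _ = roc_curve(yte, scores)
        results[int(n)] = {
            "cv_accuracy_mean": float(cv_acc.mean()),
            "cv_accuracy_sd": float(cv_acc.std(ddof=1)),
            "test_accuracy": float(accuracy_score(yte, model.predict(Xte))),
            "auc": float(_auc(fpr, tpr)),
            "roc_fpr": fpr.tolist(),
            "roc_tpr": tpr.tolist(),
            "features": [list(f) for f in ranking.top_ids(int(n))],
        }
    return ClassifierReport(results=results, seed=seed, kernel=kernel,
                            n_train=int(len(train_idx)), n_test=int(len(test_idx)),
                            cv_folds=cv_folds, group_split=group_split)


def train_and_evaluate(fs: FeatureSet, seed: int = 0, n_list=DEFAULT_TOP_N,
                       kernel: str = "rbf", n_trees: int = 500,
                       test_size: float = 0.2, cv_folds: int = 10,
                       group_split: bool = False) -> tuple[FeatureRanking, ClassifierReport]:
    """Leak-free protocol: split once, rank on the training split, score top-n SVMs."""
    train_idx, test_idx = _split(fs, seed, test_size, group_split)
    ranking = gini_rank(fs, n_trees=n_trees, seed=seed, sample_idx=train_idx)
    report = evaluate_topn(fs, ranking, n_list=n_list, seed=seed, kernel=kernel,
                           train_idx=train_idx, test_idx=test_idx,
                           cv_folds=cv_folds, group_split=group_split)
    return ranking, report
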