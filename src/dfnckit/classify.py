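"""Dynamic-FNC classification via centroid-regression features.

Feature construction: build a design whose columns are the mean
windowed-FNC patterns of each (group, state) cell (2 groups x 4 states
= 8 columns); regress every window's FNC vector on those columns
(no intercept, both sides centered across the pair dimension), giving 8
beta coefficients per window; average over windows to get 8 features
per subject. A Pearson-correlation feature variant (window vs column
correlations instead of joint regression) is available behind a flag.

Evaluation: linear SVM with repeated stratified 10-fold cross-
validation (100 repeats by default), reporting per-class accuracy
(sensitivity per group) averaged across folds and repeats, plus an ROC
from pooled decision scores. Two leakage modes exist because the
centroid design is computed from all subjects in the original design:
``paper_faithful`` does exactly that, while the default ``fold_safe``
refits the state model and design on training subjects only within each
fold, assigning held-out windows to the frozen training centroids.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.metrics import auc, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from . import states as states_mod
from .types import WindowedFNCSeries


@dataclass
class CentroidDesign:
    """n_pairs x m design; column j is the mean window of cell labels[j]."""

    matrix: np.ndarray
    labels: list[tuple[str, int]]  # (group, state)

    @property
    def n_features(self) -> int:
        return self.matrix.shape[1]


def build_centroid_design(
    series_list: list[WindowedFNCSeries],
    state_labels: dict[str, np.ndarray],
    groups: dict[str, str],
    n_states: int,
    group_order: tuple[str, str] = ("CD", "HC"),
) -> CentroidDesign:
    """Mean windowed-FNC pattern per (group, state) cell.

    Cells with no windows are dropped with a warning, shrinking the
    feature length accordingly.
    """
    n_pairs = series_list[0].n_pairs
    sums: dict[tuple[str, int], np.ndarray] = {}
    counts: dict[tuple[str, int], int] = {}
    for g in group_order:
        for s in range(1, n_states + 1):
            sums[(g, s)] = np.zeros(n_pairs)
            counts[(g, s)] = 0
    for series in series_list:
        g = groups[series.subject_id]
        labels = np.asarray(state_labels[series.subject_id])
        for s in range(1, n_states + 1):
            mask = labels == s
            if mask.any():
                sums[(g, s)] += series.data[mask].sum(axis=0)
                counts[(g, s)] += int(mask.sum())
    cols, kept = [], []
    for key in sums:
        if counts[key] == 0:
            warnings.warn(f"empty (group, state) cell {key}: column dropped")
            continue
        cols.append(sums[key] / counts[key])
        kept.append(key)
    return CentroidDesign(matrix=np.column_stack(cols), labels=kept)


def _center_pairs(A: np.ndarray) -> np.ndarray:
    """Center across the pair dimension (rows of the design / entries of
    a window vector)."""
    return A - A.mean(axis=0, keepdims=True)


def window_betas(window_vector: np.ndarray, design: CentroidDesign) -> np.ndarray:
    """OLS of one centered window vector on the centered design columns."""
    return _all_window_betas(window_vector[None, :], design)[0]


def _all_window_betas(W: np.ndarray, design: CentroidDesign) -> np.ndarray:
    D = _center_pairs(design.matrix)
    if np.allclose(D, 0):
        raise ValueError("design columns are all zero after centering")
    Wc = W - W.mean(axis=1, keepdims=True)
    if np.linalg.matrix_rank(D) < D.shape[1]:
        warnings.warn("rank-deficient centroid design; minimum-norm solution")
    beta, *_ = np.linalg.lstsq(D, Wc.T, rcond=None)
    return beta.T


def subject_features(
    series: WindowedFNCSeries, design: CentroidDesign, variant: str = "regression"
) -> np.ndarray:
    """Mean beta (or correlation) coefficients over a subject's windows."""
    if variant == "regression":
        return _all_window_betas(series.data, design).mean(axis=0)
    if variant == "correlation":
        D = _center_pairs(design.matrix)
        Wc = _center_pairs(series.data.T).T
        num = Wc @ D
        den = np.outer(
            np.linalg.norm(Wc, axis=1), np.linalg.norm(D, axis=0)
        )
        return (num / den).mean(axis=0)
    raise ValueError("variant must be 'regression' or 'correlation'")


class CentroidRegressionFeatures(TransformerMixin, BaseEstimator):
    """Transformer: windowed FNC series -> per-subject beta features.

    fit() consumes the training series plus their state labels and
    groups to build the centroid design; transform() projects any
    subject's windows onto that design and averages.
    """

    def __init__(self, n_states: int = 4,
                 group_order: tuple[str, str] = ("CD", "HC"),
                 variant: str = "regression"):
        self.n_states = n_states
        self.group_order = group_order
        self.variant = variant

    def fit(self, series_list, state_labels, groups):
        self.design_ = build_centroid_design(
            series_list, state_labels, groups, self.n_states, self.group_order
        )
        return self

    def transform(self, series_list) -> np.ndarray:
        return np.vstack(
            [subject_features(s, self.design_, self.variant) for s in series_list]
        )


@dataclass
class ClassificationResult:
    per_class_accuracy: dict[str, float]
    mean_accuracy: float
    fold_accuracies: np.ndarray = field(repr=False)
    roc_fpr: np.ndarray = field(repr=False)
    roc_tpr: np.ndarray = field(repr=False)
    auc: float
    mode: str
    n_folds: int
    n_repeats: int
    svm_c: float
    seed: int | None
    features: np.ndarray | None = field(repr=False, default=None)

    def to_jsonable(self) -> dict:
        return {
            "per_class_accuracy": self.per_class_accuracy,
            "mean_accuracy": self.mean_accuracy,
            "auc": self.auc,
            "mode": self.mode,
            "n_folds": self.n_folds,
            "n_repeats": self.n_repeats,
            "svm_c": self.svm_c,
            "seed": self.seed,
        }


def evaluate_classifier(
    features: np.ndarray,
    groups,
    folds: int = 10,
    repeats: int = 100,
    svm_c: float = 1.0,
    seed: int | None = None,
    mode: str = "precomputed",
) -> ClassificationResult:
    """Repeated stratified k-fold linear SVM on fixed subject features."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(groups)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")
    rng = np.random.default_rng(seed)
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    fold_acc = []
    scores_all, truth_all = [], []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for train, test in skf.split(X, y):
            clf = SVC(kernel="linear", C=svm_c)
            clf.fit(X[train], y[train])
            pred = clf.predict(X[test])
            fold_acc.append(float((pred == y[test]).mean()))
            for c in classes:
                m = y[test] == c
                correct[c] += int((pred[m] == c).sum())
                total[c] += int(m.sum())
            scores_all.append(clf.decision_function(X[test]))
            truth_all.append(y[test] == classes[1])
    per_class = {str(c): correct[c] / total[c] for c in classes}
    fpr, tpr, _ = roc_curve(np.concatenate(truth_all), np.concatenate(scores_all))
    return ClassificationResult(
        per_class_accuracy=per_class,
        mean_accuracy=float(np.mean(list(per_class.values()))),
        fold_accuracies=np.asarray(fold_acc),
        roc_fpr=fpr, roc_tpr=tpr, auc=float(auc(fpr, tpr)),
        mode=mode, n_folds=folds, n_repeats=repeats, svm_c=svm_c, seed=seed,
        features=X,
    )


def evaluate_dfnc_classifier(
    series_list: list[WindowedFNCSeries],
    groups: dict[str, str],
    n_states: int = 4,
    mode: str = "fold_safe",
    state_labels: dict[str, np.ndarray] | None = None,
    folds: int = 10,
    repeats: int = 100,
    svm_c: float = 1.0,
    seed: int | None = None,
    variant: str = "regression",
    group_order: tuple[str, str] = ("CD", "HC"),
    kmeans_n_init: int = 5,
) -> ClassificationResult:
    """End-to-end classification from windowed FNC series.

    paper_faithful: centroid design from all subjects once (requires
    ``state_labels`` from a full-cohort state model); fold_safe: per
    fold, refit states and design on training subjects only and assign
    test windows to the frozen training centroids.
    """
    if mode not in {"paper_faithful", "fold_safe"}:
        raise ValueError("mode must be 'paper_faithful' or 'fold_safe'")
    y = np.asarray([groups[s.subject_id] for s in series_list])
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required")

    if mode == "paper_faithful":
        if state_labels is None:
            model = states_mod.fit_states(series_list, k=n_states,
                                          n_init=kmeans_n_init, seed=seed)
            state_labels = model.labels
        feats = CentroidRegressionFeatures(n_states, group_order, variant).fit(
            series_list, state_labels, groups
        ).transform(series_list)
        res = evaluate_classifier(feats, y, folds, repeats, svm_c, seed, mode)
        return res

    rng = np.random.default_rng(seed)
    correct = {c: 0 for c in classes}
    total = {c: 0 for c in classes}
    fold_acc = []
    scores_all, truth_all = [], []
    feats_last = None
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for train, test in skf.split(np.zeros(len(series_list)), y):
            train_series = [series_list[i] for i in train]
            model = states_mod.fit_states(
                train_series, k=n_states, n_init=kmeans_n_init,
                seed=int(rng.integers(2**31 - 1)),
            )
            all_labels = dict(model.labels)
            all_labels.update(
                states_mod.assign_states(
                    [series_list[i] for i in test], model.centroids
                )
            )
            extractor = CentroidRegressionFeatures(
                n_states, group_order, variant
            ).fit(train_series, all_labels, groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # sparse cells in small folds
                Xtr = extractor.transform(train_series)
                Xte = extractor.transform([series_list[i] for i in test])
            clf = SVC(kernel="linear", C=svm_c)
            clf.fit(Xtr, y[train])
            pred = clf.predict(Xte)
            fold_acc.append(float((pred == y[test]).mean()))
            for c in classes:
                m = y[test] == c
                correct[c] += int((pred[m] == c).sum())
                total[c] += int(m.sum())
            scores_all.append(clf.decision_function(Xte))
            truth_all.append(y[test] == classes[1])
            feats_last = Xtr
    per_class = {str(c): correct[c] / total[c] for c in classes}
    fpr, tpr, _ = roc_curve(np.concatenate(truth_all), np.concatenate(scores_all))
    return ClassificationResult(
        per_class_accuracy=per_class,
        mean_accuracy=float(np.mean(list(per_class.values()))),
        fold_accuracies=np.asarray(fold_acc),
        roc_fpr=fpr, roc_tpr=tpr, auc=float(auc(fpr, tpr)),
        mode=mode, n_folds=folds, n_repeats=repeats, svm_c=svm_c, seed=seed,
        features=feats_last,
    )
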