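"""Classifier training and evaluation under nested stratified cross-validation.

The protocol: an outer stratified k-fold loop estimates generalization
performance; on each outer training portion an inner stratified k-fold loop
selects the hyperparameter grid point with the best mean AUC.  Feature
standardization is estimated on training portions only (never on held-out
data) unless the leakage-mimicking ``global_standardize`` flag is set.
Ties in the inner loop go to the smallest (most regularized) grid point.
"""

from __future__ import annotations

import pickle
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn import metrics as skmetrics
from sklearn.exceptions import ConvergenceWarning
from sklearn.discriminant_analysis import (
    LinearDiscriminantAnalysis,
    QuadraticDiscriminantAnalysis,
)
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier, NearestCentroid
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .featmat import FeatureMatrix
from .seqdata import Labeling

CLASSIFIER_KINDS = (
    "svm_linear", "svm_rbf", "knn_uniform", "knn_distance", "nearest_centroid",
    "lda", "qda", "gaussian_nb", "decision_tree", "random_forest",
)

_KNN_K = (1, 2, 3, 4, 5, 10, 20, 30, 40, 50, 100)

#: hyperparameter search grids, ordered smallest-first for tie-breaking.
GRIDS: dict[str, list[dict]] = {
    "svm_linear": [{"C": 10.0 ** e} for e in range(-3, 4)],
    "svm_rbf": [
        {"C": 10.0 ** ce, "gamma": 10.0 ** ge}
        for ce in (-1, 0, 1) for ge in (-1, 0, 1)
    ],
    "knn_uniform": [{"n_neighbors": k} for k in _KNN_K],
    "knn_distance": [{"n_neighbors": k} for k in _KNN_K],
    "nearest_centroid": [{"shrink_threshold": float(r)} for r in range(1, 11)],
    "lda": [],
    "qda": [],
    "gaussian_nb": [],
    "decision_tree": [],
    "random_forest": [],
}


@dataclass(frozen=True)
class ClassifierSpec:
    kind: str
    grid: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(
                f"unknown classifier kind {self.kind!r}; "
                f"choose from {CLASSIFIER_KINDS}"
            )
        if self.grid is None:
            object.__setattr__(self, "grid", tuple(GRIDS[self.kind]))


@dataclass(frozen=True)
class CVConfig:
    k_outer: int = 10
    k_inner: int | None = None  # defaults to k_outer
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_outer < 2:
            raise ValueError("k_outer must be >= 2")
        if self.k_inner is not None and self.k_inner < 2:
            raise ValueError("k_inner must be >= 2")

    @property
    def inner(self) -> int:
        return self.k_inner if self.k_inner is not None else self.k_outer


# libsvm has no default iteration cap; large-C fits on unseparable data can
# otherwise take minutes without measurably changing the decision function
_SVM_MAX_ITER = 100_000


def make_estimator(kind: str, params: dict, seed: int = 0):
    """Instantiate an unfitted scikit-learn estimator for ``kind``."""
    if kind == "svm_linear":
        return SVC(kernel="linear", random_state=seed,
                   max_iter=_SVM_MAX_ITER, **params)
    if kind == "svm_rbf":
        return SVC(kernel="rbf", random_state=seed,
                   max_iter=_SVM_MAX_ITER, **params)
    if kind == "knn_uniform":
        return KNeighborsClassifier(weights="uniform", **params)
    if kind == "knn_distance":
        return KNeighborsClassifier(weights="distance", **params)
    if kind == "nearest_centroid":
        return NearestCentroid(**params)
    if kind == "lda":
        return LinearDiscriminantAnalysis(**params)
    if kind == "qda":
        return QuadraticDiscriminantAnalysis(**params)
    if kind == "gaussian_nb":
        return GaussianNB(**params)
    if kind == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **params)
    if kind == "random_forest":
        return RandomForestClassifier(random_state=seed, **params)
    raise ValueError(kind)


# ---------------------------------------------------------------------------
# folds, scores, ROC


def stratified_folds(labels, k: int, seed: int = 0) -> list[np.ndarray]:
    """Disjoint, exhaustive index folds preserving class proportions."""
    labels = np.asarray(labels)
    _, counts = np.unique(labels, return_counts=True)
    if k > counts.min():
        raise ValueError(
            f"k={k} exceeds the smallest class size ({counts.min()})"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return [test for _, test in skf.split(np.zeros(len(labels)), labels)]


def _decision_scores(est, X: np.ndarray, positive: str) -> np.ndarray:
    """Per-sample score for the positive class.

    Signed distance to the decision boundary where available, otherwise the
    positive-class probability; for score-less classifiers (nearest
    centroid) the negated distance to the positive centroid margin proxy is
    unavailable, so 0/1 predictions are used as scores.
    """
    classes = list(est.classes_)
    pos_idx = classes.index(positive)
    if hasattr(est, "decision_function"):
        s = est.decision_function(X)
        if s.ndim == 1:
            return s if pos_idx == 1 else -s
        return s[:, pos_idx]
    if hasattr(est, "predict_proba"):
        return est.predict_proba(X)[:, pos_idx]
    return (est.predict(X) == positive).astype(float)


def roc_curve(scores, truth, positive: str):
    """ROC by descending-score sweep plus trapezoidal AUC.

    Returns ``(fpr, tpr, auc)``.  Requires both classes present.
    """
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    y = truth == positive
    if y.all() or not y.any():
        raise ValueError("ROC needs both classes present in the truth labels")
    fpr, tpr, _ = skmetrics.roc_curve(y.astype(int), scores)
    return fpr, tpr, float(skmetrics.auc(fpr, tpr))


def average_roc(curves, grid_points: int = 101):
    """Vertically average per-fold ROC curves on a fixed FPR grid."""
    grid = np.linspace(0.0, 1.0, grid_points)
    tprs = [np.interp(grid, fpr, tpr) for fpr, tpr in curves]
    return grid, np.mean(tprs, axis=0)


# ---------------------------------------------------------------------------
# standardization inside the CV loop (population sd, constant columns kept
# out of the transform by unit sd substitution so fold feature sets agree)


def _fit_standardizer(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    sd = np.where(sd == 0.0, 1.0, sd)
    return mean, sd


def _fit(est, X, y):
    """Fit while silencing iteration-cap warnings from bounded SVM solves."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        est.fit(X, y)
    return est


def _fold_auc(y_true, scores, positive: str) -> float:
    _, _, a = roc_curve(scores, y_true, positive)
    return a


def _macro_ovr_auc(est, X, y) -> float:
    classes = list(est.classes_)
    if hasattr(est, "predict_proba"):
        S = est.predict_proba(X)
    else:
        S = est.decision_function(X)
    aucs = []
    for i, c in enumerate(classes):
        yc = (np.asarray(y) == c).astype(int)
        if yc.all() or not yc.any():
            continue
        aucs.append(skmetrics.roc_auc_score(yc, S[:, i]))
    return float(np.mean(aucs))


@dataclass
class FoldResult:
    fold: int
    train_idx: np.ndarray
    test_idx: np.ndarray
    chosen_params: dict
    auc: float
    accuracy: float
    precision: float
    recall: float
    f1: float
    roc_fpr: np.ndarray | None
    roc_tpr: np.ndarray | None
    #: standardization parameters used to transform this fold's test data
    standardization: tuple[np.ndarray, np.ndarray] | None = None


@dataclass
class TrainedModel:
    """A fitted classifier bundled with everything needed to apply it."""

    format_version: int
    kind: str
    params: dict
    estimator: object
    feature_names: list[str]
    standardization: tuple[np.ndarray, np.ndarray] | None
    class_names: list[str]
    positive_class: str | None

    def save(self, path: str | Path) -> None:
        with open(path, "wb") as fh:
            pickle.dump(self, fh)

    @staticmethod
    def load(path: str | Path) -> "TrainedModel":
        with open(path, "rb") as fh:
            model = pickle.load(fh)
        if not isinstance(model, TrainedModel):
            raise ValueError(f"{path} is not a protfeat model file")
        return model


@dataclass
class CVResult:
    folds: list[FoldResult]
    summary: dict[str, float]
    model: TrainedModel
    average_roc: tuple[np.ndarray, np.ndarray] | None = None
    feature_names: list[str] = field(default_factory=list)

    @property
    def mean_auc(self) -> float:
        return self.summary["auc_mean"]


def _select_params(X, y, spec: ClassifierSpec, k: int, seed: int,
                   positive: str | None, multiclass: bool) -> dict:
    """Inner-loop grid selection: best mean stratified-CV AUC, smallest-first
    tie-breaking.  Parameterless classifiers return an empty dict."""
    if not spec.grid:
        return {}
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    splits = list(skf.split(X, y))
    best_params, best_auc = None, -np.inf
    for params in spec.grid:
        aucs = []
        try:
            for tr, te in splits:
                mean, sd = _fit_standardizer(X[tr])
                est = make_estimator(spec.kind, params, seed)
                _fit(est, (X[tr] - mean) / sd, y[tr])
                Z = (X[te] - mean) / sd
                if multiclass:
                    aucs.append(_macro_ovr_auc(est, Z, y[te]))
                else:
                    aucs.append(_fold_auc(
                        y[te], _decision_scores(est, Z, positive), positive))
        except ValueError:
            continue  # e.g. k-NN with more neighbors than training samples
        mean_auc = float(np.mean(aucs))
        if mean_auc > best_auc:  # strict: earlier (smaller) grid points win ties
            best_auc, best_params = mean_auc, params
    if best_params is None:
        raise ValueError(
            f"no feasible grid point for {spec.kind} with the given data size"
        )
    return best_params


def train_cv(fm: FeatureMatrix, labeling: Labeling, spec: ClassifierSpec,
             cv: CVConfig, feature_subset: list[str] | None = None,
             global_standardize: bool = False) -> CVResult:
    """Nested stratified cross-validation optimizing AUC, then a final fit.

    Per outer fold, the grid point with the best mean inner-fold AUC is
    selected, the model is refit on the outer training portion and scored
    on the held-out fold.  The final model is trained on all labeled data
    with parameters selected by one more inner-style loop over it.

    ``global_standardize=True`` standardizes once on the full matrix before
    any splitting (a deliberately leaky mode kept for comparison only).
    """
    if len(labeling.class_names) < 2:
        raise ValueError("classification needs at least 2 classes")
    features = feature_subset or fm.feature_names
    missing = [f for f in features if f not in fm.data.columns]
    if missing:
        raise ValueError(f"unknown features requested: {missing}")
    ids = [i for i in fm.ids if i in labeling.assignments]
    X_all = fm.data.loc[ids, features].to_numpy(float)
    y_all = np.array([labeling.assignments[i] for i in ids])
    classes = sorted(labeling.class_names)
    multiclass = len(classes) > 2
    positive = None if multiclass else classes[1]

    if global_standardize:
        gmean, gsd = _fit_standardizer(X_all)
        X_all = (X_all - gmean) / gsd

    outer = StratifiedKFold(n_splits=cv.k_outer, shuffle=True,
                            random_state=cv.seed)
    folds: list[FoldResult] = []
    curves = []
    for f, (tr, te) in enumerate(outer.split(X_all, y_all)):
        X_tr, y_tr = X_all[tr], y_all[tr]
        X_te, y_te = X_all[te], y_all[te]
        params = _select_params(X_tr, y_tr, spec, cv.inner, cv.seed,
                                positive, multiclass)
        if global_standardize:
            mean, sd = np.zeros(X_tr.shape[1]), np.ones(X_tr.shape[1])
        else:
            mean, sd = _fit_standardizer(X_tr)
        est = make_estimator(spec.kind, params, cv.seed)
        _fit(est, (X_tr - mean) / sd, y_tr)
        Z_te = (X_te - mean) / sd
        y_pred = est.predict(Z_te)
        if multiclass:
            auc_val = _macro_ovr_auc(est, Z_te, y_te)
            fpr = tpr = None
            prec, rec, f1v = (
                skmetrics.precision_score(y_te, y_pred, average="macro",
                                          zero_division=0),
                skmetrics.recall_score(y_te, y_pred, average="macro",
                                       zero_division=0),
                skmetrics.f1_score(y_te, y_pred, average="macro",
                                   zero_division=0),
            )
        else:
            scores = _decision_scores(est, Z_te, positive)
            fpr, tpr, auc_val = roc_curve(scores, y_te, positive)
            curves.append((fpr, tpr))
            prec = skmetrics.precision_score(y_te, y_pred, pos_label=positive,
                                             zero_division=0)
            rec = skmetrics.recall_score(y_te, y_pred, pos_label=positive,
                                         zero_division=0)
            f1v = skmetrics.f1_score(y_te, y_pred, pos_label=positive,
                                     zero_division=0)
        folds.append(FoldResult(
            fold=f, train_idx=tr, test_idx=te, chosen_params=params,
            auc=float(auc_val),
            accuracy=float(skmetrics.accuracy_score(y_te, y_pred)),
            precision=float(prec), recall=float(rec), f1=float(f1v),
            roc_fpr=fpr, roc_tpr=tpr,
            standardization=(mean, sd),
        ))

    summary = {}
    for m in ("auc", "accuracy", "precision", "recall", "f1"):
        vals = np.array([getattr(fr, m) for fr in folds])
        summary[f"{m}_mean"] = float(vals.mean())
        summary[f"{m}_sd"] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0

    # final model: parameters re-optimized on all labeled data, then fit on it
    final_params = _select_params(X_all, y_all, spec, cv.inner, cv.seed,
                                  positive, multiclass)
    if global_standardize:
        fmean, fsd = gmean, gsd
        Z_full = X_all
    else:
        fmean, fsd = _fit_standardizer(X_all)
        Z_full = (X_all - fmean) / fsd
    final_est = make_estimator(spec.kind, final_params, cv.seed)
    _fit(final_est, Z_full, y_all)
    model = TrainedModel(
        format_version=1, kind=spec.kind, params=final_params,
        estimator=final_est, feature_names=list(features),
        standardization=(fmean, fsd), class_names=classes,
        positive_class=positive,
    )
    avg = average_roc(curves) if curves else None
    return CVResult(folds=folds, summary=summary, model=model,
                    average_roc=avg, feature_names=list(features))


def predict(model: TrainedModel, fm: FeatureMatrix) -> pd.DataFrame:
    """Apply a trained model; rows are transformed with the model's stored
    standardization.  Missing feature columns are reported by name."""
    missing = [f for f in model.feature_names if f not in fm.data.columns]
    if missing:
        raise ValueError(f"feature matrix lacks model features: {missing}")
    X = fm.data[model.feature_names].to_numpy(float)
    mean, sd = model.standardization
    Z = (X - mean) / sd
    labels = model.estimator.predict(Z)
    if model.positive_class is not None:
        scores = _decision_scores(model.estimator, Z, model.positive_class)
    else:
        scores = np.full(len(labels), np.nan)
    return pd.DataFrame({"label": labels, "score": scores},
                        index=pd.Index(fm.ids, name="id"))
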