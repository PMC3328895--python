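"""The five classifier families and cross-validated accuracy evaluation.

Classifiers: Gaussian Naive Bayes (NB), a logistic model tree (LMT: a
shallow CART partition with multinomial logistic models at the leaves —
an approximation of full LMT induction), a single random tree (RT), a
random forest (RF) and an RBF-kernel SVM with an inner grid search over
(C, γ).  Accuracies come from stratified k-fold cross-validation and are
reported as percentages.  NB and SVM see z-scored features; the scaler is
fitted on each training fold only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

CLASSIFIER_IDS = ("NB", "LMT", "RT", "RF", "SVM")

#: Default seed for stratified CV shuffling.
DEFAULT_CV_SEED = 20120405

GUILLON_LABELS = ("open_meshwork", "closed_meshwork", "wave", "colour_fringe")


@dataclass(frozen=True)
class LabelledDataset:
    """Descriptor matrix with one Guillon label per row."""

    X: np.ndarray
    y: np.ndarray
    image_ids: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        X = np.asarray(self.X, dtype=np.float64)
        y = np.asarray(self.y)
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.isfinite(X).all():
            raise ValueError("X contains non-finite entries")
        if y.shape[0] != X.shape[0]:
            raise ValueError("X and y length mismatch")
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            raise ValueError("every class needs at least 2 members")
        object.__setattr__(self, "X", X)
        object.__setattr__(self, "y", y)

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass(frozen=True)
class CVResult:
    classifier_id: str
    accuracy: float                  # percentage, fold-size-weighted mean
    fold_accuracies: tuple[float, ...]
    fold_sizes: tuple[int, ...]
    seed: int


class LogisticModelTree(BaseEstimator, ClassifierMixin):
    """Shallow decision tree with multinomial logistic models at the leaves.

    Leaves with a single class (or too few samples to fit a regression)
    predict their majority class directly.
    """

    def __init__(self, max_depth: int = 3, min_leaf: int = 5,
                 C: float = 1.0, random_state: int | None = None):
        self.max_depth = max_depth
        self.min_leaf = min_leaf
        self.C = C
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self.tree_ = DecisionTreeClassifier(
            max_depth=self.max_depth,
            min_samples_leaf=max(self.min_leaf, 1),
            random_state=self.random_state,
        ).fit(X, y)
        leaves = self.tree_.apply(X)
        self.leaf_models_ = {}
        for leaf in np.unique(leaves):
            idx = leaves == leaf
            y_leaf = y[idx]
            if np.unique(y_leaf).size < 2 or idx.sum() < self.min_leaf:
                vals, counts = np.unique(y_leaf, return_counts=True)
                self.leaf_models_[int(leaf)] = vals[np.argmax(counts)]
            else:
                lr = LogisticRegression(C=self.C, max_iter=1000)
                self.leaf_models_[int(leaf)] = lr.fit(X[idx], y_leaf)
        return self

    def predict(self, X):
        check_is_fitted(self, "tree_")
        X = np.asarray(X, dtype=np.float64)
        leaves = self.tree_.apply(X)
        out = np.empty(X.shape[0], dtype=self.classes_.dtype)
        for leaf in np.unique(leaves):
            idx = leaves == leaf
            model = self.leaf_models_[int(leaf)]
            out[idx] = model.predict(X[idx]) if hasattr(model, "predict") else model
        return out


def make_classifier(classifier_id: str, seed: int | None = None, **hyperparams):
    """Build a trainable model (fit/predict) for one of the five families.

    NB and SVM are wrapped in a pipeline with a standard scaler so that
    standardisation is refitted on every training fold.  SVM runs an
    inner 5-fold grid search over C ∈ {1e-1..1e3}, γ ∈ {1e-4..1e1}.
    """
    cid = classifier_id.upper()
    if cid == "NB":
        return Pipeline([("scale", StandardScaler()), ("nb", GaussianNB(**hyperparams))])
    if cid == "LMT":
        return LogisticModelTree(random_state=seed, **hyperparams)
    if cid == "RT":
        params = {"max_features": "sqrt"} | hyperparams
        return DecisionTreeClassifier(random_state=seed, **params)
    if cid == "RF":
        params = {"n_estimators": 100, "max_features": "sqrt"} | hyperparams
        return RandomForestClassifier(random_state=seed, **params)
    if cid == "SVM":
        grid = hyperparams.pop("param_grid", None) or {
            "C": [0.1, 1.0, 10.0, 100.0, 1000.0],
            "gamma": [1e-4, 1e-3, 1e-2, 1e-1, 1.0, 10.0],
        }
        svc = SVC(kernel="rbf", decision_function_shape="ovo", **hyperparams)
        search = GridSearchCV(
            svc,
            grid,
            cv=StratifiedKFold(5, shuffle=True, random_state=seed),
            n_jobs=1,
        )
        return Pipeline([("scale", StandardScaler()), ("svm", search)])
    raise ValueError(f"unknown classifier id {classifier_id!r}")


def crossval_accuracy(
    data: LabelledDataset,
    classifier_id: str,
    k: int = 10,
    seed: int = DEFAULT_CV_SEED,
) -> CVResult:
    """Stratified k-fold cross-validated accuracy (percentage).

    The overall accuracy is the fold-size-weighted mean of per-fold
    accuracies, i.e. the overall fraction of correct test predictions.
    When a class has fewer members than folds, stratification degrades to
    scikit-learn's behaviour of spreading the class as evenly as possible.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if data.n < k:
        raise ValueError("fewer samples than folds")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_acc: list[float] = []
    fold_sizes: list[int] = []
    model = make_classifier(classifier_id, seed=seed)
    for train, test in skf.split(data.X, data.y):
        m = clone(model)
        m.fit(data.X[train], data.y[train])
        pred = m.predict(data.X[test])
        fold_acc.append(float(np.mean(pred == data.y[test]) * 100.0))
        fold_sizes.append(test.size)
    total = sum(fold_sizes)
    overall = float(sum(a * s for a, s in zip(fold_acc, fold_sizes)) / total)
    return CVResult(classifier_id.upper(), overall, tuple(fold_acc), tuple(fold_sizes), seed)


def accuracy_table(
    datasets: dict[str, LabelledDataset],
    classifiers=CLASSIFIER_IDS,
    k: int = 10,
    seed: int = DEFAULT_CV_SEED,
    colour_space: str = "",
    method: str = "",
):
    """Classifiers × conditions table of CV accuracies (with Avg. on demand)."""
    from .tables import accuracy_table_from_results

    if not datasets:
        raise ValueError("no datasets supplied")
    results = {
        cid: {cond: crossval_accuracy(ds, cid, k=k, seed=seed).accuracy
              for cond, ds in datasets.items()}
        for cid in classifiers
    }
    return accuracy_table_from_results(results, colour_space, method)
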