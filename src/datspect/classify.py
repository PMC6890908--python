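"""Standardization, stratified splitting and the linear-SVM combiner.

The combiner is a soft-margin linear SVM (hinge loss + L2 penalty) on
z-scored features, W.x' + b, with the regularization strength selected from
a grid by stratified k-fold cross-validated accuracy on the training part
only.  It is exposed as a scikit-learn compatible estimator so it composes
with pipelines and model selection; the module-level functions are thin
wrappers kept for script use.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

POSITIVE_LABEL = 1  # PS (disease) is the positive class

DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0, 100.0)


@dataclass(frozen=True)
class StandardizationParams:
    """Per-feature training mean and standard deviation, x' = (x - mean)/sd."""

    mean: np.ndarray
    sd: np.ndarray

    def apply(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.mean) / self.sd


def standardize_fit(train_matrix: np.ndarray) -> StandardizationParams:
    X = np.asarray(train_matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("training matrix must be 2-D with at least 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)  # population SD; the transformed columns get unit variance
    if (sd <= 0).any():
        bad = np.where(sd <= 0)[0].tolist()
        raise ValueError(f"constant feature(s) at column(s) {bad}; cannot standardize")
    return StandardizationParams(mean=mean, sd=sd)


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint, exhaustive train/test index lists with stratification metadata."""

    train_ids: list
    test_ids: list
    test_fraction: float
    stratified: bool
    seed: int


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


def stratified_split(labels, test_fraction: float, seed: int, ids=None) -> SplitPlan:
    """Per-class test counts are round(fraction * class size); seeded shuffle."""
    labels = np.asarray(labels)
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    classes, counts = np.unique(labels, return_counts=True)
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 members to split")
    if ids is None:
        ids = np.arange(len(labels))
    ids = np.asarray(ids)
    rng = np.random.default_rng(seed)
    test_idx: list[int] = []
    for cls, n_cls in zip(classes, counts):
        members = np.where(labels == cls)[0]
        n_test = _round_half_up(test_fraction * n_cls)
        n_test = min(max(n_test, 1), n_cls - 1)  # keep both parts non-empty per class
        chosen = rng.permutation(members)[:n_test]
        test_idx.extend(chosen.tolist())
    test_set = set(test_idx)
    train_idx = [i for i in range(len(labels)) if i not in test_set]
    return SplitPlan(
        train_ids=ids[train_idx].tolist(),
        test_ids=ids[sorted(test_set)].tolist(),
        test_fraction=test_fraction,
        stratified=True,
        seed=seed,
    )


def _canonical_order(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Row order independent of input permutation (label, then feature columns)."""
    keys = tuple(X[:, j] for j in reversed(range(X.shape[1]))) + (y,)
    return np.lexsort(keys)


class StandardizedLinearSVM(BaseEstimator, ClassifierMixin):
    """Linear SVM on z-scored features with CV-selected regularization.

    Parameters
    ----------
    c_grid : iterable of float
        Candidate soft-margin strengths; ties in CV accuracy resolve to the
        smallest C.
    k_folds : int
        Stratified CV folds used for selection (must not exceed the smaller
        class size).
    random_state : int
        Seed for the CV fold shuffle.  Rows are canonically re-ordered before
        folding and fitting, so the fit does not depend on input row order.

    Attributes
    ----------
    classes_ : array of the two class labels, positive class last.
    mean_, scale_ : standardization parameters estimated on the training data.
    coef_, intercept_ : hyperplane W and b in standardized feature space.
    C_ : selected regularization strength.
    cv_scores_ : mean CV accuracy per candidate C.
    cv_folds_ : fold assignment per (canonically ordered) training row.
    """

    def __init__(self, c_grid=DEFAULT_C_GRID, k_folds: int = 10, random_state: int = 0):
        self.c_grid = c_grid
        self.k_folds = k_folds
        self.random_state = random_state

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = self._encode_labels(np.asarray(y))
        if X.ndim != 2:
            raise ValueError("X must be 2-D")
        classes, counts = np.unique(y, return_counts=True)
        if len(classes) != 2:
            raise ValueError("training data must contain exactly two classes")
        if self.k_folds > counts.min():
            raise ValueError(
                f"k_folds={self.k_folds} exceeds the smaller class size {counts.min()}"
            )
        order = _canonical_order(X, y)
        X, y = X[order], y[order]

        params = standardize_fit(X)
        Xs = params.apply(X)

        c_grid = sorted(float(c) for c in self.c_grid)
        skf = StratifiedKFold(
            n_splits=self.k_folds, shuffle=True, random_state=self.random_state
        )
        folds = list(skf.split(Xs, y))
        accuracies = []
        for c in c_grid:
            correct = 0
            for tr, te in folds:
                clf = SVC(kernel="linear", C=c)
                clf.fit(Xs[tr], y[tr])
                correct += (clf.predict(Xs[te]) == y[te]).sum()
            accuracies.append(correct / len(y))
        best = int(np.argmax(accuracies))  # argmax takes the first (smallest C) on ties

        final = SVC(kernel="linear", C=c_grid[best])
        final.fit(Xs, y)

        self.classes_ = np.array([0, 1])
        self.mean_ = params.mean
        self.scale_ = params.sd
        self.C_ = c_grid[best]
        self.cv_scores_ = dict(zip(c_grid, accuracies))
        fold_assign = np.empty(len(y), dtype=int)
        for f, (_, te) in enumerate(folds):
            fold_assign[te] = f
        self.cv_folds_ = fold_assign
        self.coef_ = final.coef_[0].copy()
        self.intercept_ = float(final.intercept_[0])
        self.n_features_in_ = X.shape[1]
        return self

    @staticmethod
    def _encode_labels(y):
        if y.dtype.kind in "UO":
            mapping = {"NPS": 0, "PS": 1}
            try:
                return np.array([mapping[v] for v in y])
            except KeyError as err:
                raise ValueError(f"unknown class label {err.args[0]!r}") from None
        return y.astype(int)

    def decision_function(self, X):
        """Signed distance score W.x' + b; positive values point to PS."""
        check_is_fitted(self, "coef_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"expected {self.n_features_in_} features, got {X.shape[1]}"
            )
        Xs = (X - self.mean_) / self.scale_
        return Xs @ self.coef_ + self.intercept_

    def predict(self, X):
        return (self.decision_function(X) > 0).astype(int)

    # --- JSON round trip ------------------------------------------------------

    def to_json(self) -> dict:
        check_is_fitted(self, "coef_")
        return {
            "weights": self.coef_.tolist(),
            "bias": self.intercept_,
            "standardization": {"mean": self.mean_.tolist(), "sd": self.scale_.tolist()},
            "C": self.C_,
            "c_grid": list(self.c_grid),
            "k_folds": self.k_folds,
            "random_state": self.random_state,
            "cv_scores": {str(k): v for k, v in self.cv_scores_.items()},
        }

    @classmethod
    def from_json(cls, payload: dict) -> "StandardizedLinearSVM":
        model = cls(
            c_grid=tuple(payload["c_grid"]),
            k_folds=payload["k_folds"],
            random_state=payload["random_state"],
        )
        model.coef_ = np.asarray(payload["weights"], dtype=float)
        model.intercept_ = float(payload["bias"])
        model.mean_ = np.asarray(payload["standardization"]["mean"], dtype=float)
        model.scale_ = np.asarray(payload["standardization"]["sd"], dtype=float)
        model.C_ = float(payload["C"])
        model.cv_scores_ = {float(k): v for k, v in payload["cv_scores"].items()}
        model.classes_ = np.array([0, 1])
        model.n_features_in_ = len(model.coef_)
        return model

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_json(), indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "StandardizedLinearSVM":
        return cls.from_json(json.loads(Path(path).read_text()))


def fit_linear_svm(
    train_matrix,
    train_labels,
    c_grid=DEFAULT_C_GRID,
    k_folds: int = 10,
    seed: int = 0,
) -> StandardizedLinearSVM:
    return StandardizedLinearSVM(c_grid=c_grid, k_folds=k_folds, random_state=seed).fit(
        train_matrix, train_labels
    )


def decision_score(model: StandardizedLinearSVM, features) -> float | np.ndarray:
    scores = model.decision_function(features)
    return float(scores[0]) if np.asarray(features).ndim == 1 else scores
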