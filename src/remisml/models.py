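"""Base-learner registry and the two estimator classes of the pipeline.

Six base learners predict remission from the selected features: penalized
logistic regression (l1 / l2 / elastic-net as one model whose penalty type is
a grid dimension), random forest, gradient-boosted trees, XGBoost, an RBF
support-vector machine, and a small feed-forward neural network.
:class:`NestedSearchClassifier` wraps any of them with an inner 3-fold grid
search; :class:`StackingBinaryClassifier` is the level-1 logistic meta-model
over base-model probabilities.  Both are scikit-learn estimators and compose
with sklearn model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted, validate_data
from xgboost import XGBClassifier

__all__ = [
    "MODELING_MODELS",
    "SELECTION_MODELS",
    "make_base_estimator",
    "default_grid",
    "NestedSearchClassifier",
    "StackingBinaryClassifier",
]

# six modeling learners vs six selection-stage learners (lasso and ridge are
# ranked separately at selection time; gradient boosting replaces them in the
# modeling stage)
MODELING_MODELS = (
    "random_forest",
    "gradient_boosting",
    "penalized_logistic",
    "xgboost",
    "svm",
    "neural_network",
)
SELECTION_MODELS = (
    "random_forest",
    "lasso",
    "ridge",
    "xgboost",
    "svm",
    "neural_network",
)


class UnknownModelError(ValueError):
    pass


class UnfittableError(ValueError):
    """Training labels contain a single class."""


def make_base_estimator(model_id: str, seed: int = 0, fast: bool = False):
    """Instantiate one base learner with sensible defaults.

    ``fast=True`` shrinks ensemble sizes and iteration caps for desk-scale
    simulation studies; it never changes the model family.
    """
    # penalty type is expressed through l1_ratio: 0 = ridge, 1 = lasso,
    # in between = elastic net
    if model_id == "penalized_logistic":
        return LogisticRegression(
            l1_ratio=0.0, C=1.0, solver="saga", max_iter=200 if fast else 1000,
            tol=1e-3, random_state=seed,
        )
    if model_id == "lasso":
        return LogisticRegression(
            l1_ratio=1.0, C=1.0, solver="liblinear", max_iter=500, random_state=seed
        )
    if model_id == "ridge":
        return LogisticRegression(
            l1_ratio=0.0, C=1.0, solver="liblinear", max_iter=500, random_state=seed
        )
    if model_id == "random_forest":
        return RandomForestClassifier(
            n_estimators=25 if fast else 100, random_state=seed, n_jobs=1
        )
    if model_id == "gradient_boosting":
        return GradientBoostingClassifier(
            n_estimators=25 if fast else 100, random_state=seed
        )
    if model_id == "xgboost":
        return XGBClassifier(
            n_estimators=20 if fast else 100,
            max_depth=3,
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
            eval_metric="logloss",
            random_state=seed,
        )
    if model_id == "svm":
        return SVC(kernel="rbf", C=1.0, probability=True, random_state=seed)
    if model_id == "neural_network":
        return MLPClassifier(
            hidden_layer_sizes=(8,) if fast else (16,),
            max_iter=80 if fast else 400,
            alpha=1e-2,
            random_state=seed,
        )
    raise UnknownModelError(model_id)


def default_grid(model_id: str, fast: bool = False) -> dict:
    """Small documented hyperparameter grids for the nested 3-fold search."""
    if model_id == "penalized_logistic":
        if fast:
            return {"l1_ratio": [0.0, 1.0], "C": [0.1, 1.0]}
        return {"l1_ratio": [0.0, 0.5, 1.0], "C": list(np.logspace(-2, 2, 5))}
    if model_id in ("lasso", "ridge"):
        return {"C": [0.1, 1.0] if fast else [0.01, 0.1, 1.0, 10.0]}
    if model_id in ("random_forest", "gradient_boosting", "xgboost"):
        return {"max_depth": [2, 3] if fast else [2, 3, 4]}
    if model_id == "svm":
        return {"C": [0.1, 1.0] if fast else [0.1, 1.0, 10.0]}
    if model_id == "neural_network":
        if fast:
            return {"alpha": [1e-2]}
        return {"hidden_layer_sizes": [(8,), (16,)], "alpha": [1e-4, 1e-2]}
    raise UnknownModelError(model_id)


def _grid_size(grid) -> int:
    grids = grid if isinstance(grid, (list, tuple)) else [grid]
    total = 0
    for g in grids:
        size = 1
        for v in g.values():
            size *= len(v)
        total += size
    return total


class NestedSearchClassifier(BaseEstimator, ClassifierMixin):
    """One base learner tuned by an inner stratified K-fold grid search.

    With a single-configuration grid the inner search is skipped and the
    configuration is fitted directly, so a degenerate grid is exactly a
    plain fit.

    Attributes (after fit)
    ----------------------
    best_estimator_ : fitted sklearn estimator
    best_params_ : dict
    classes_ : ndarray
    """

    def __init__(
        self,
        model_id: str = "penalized_logistic",
        grid: dict | None = None,
        inner_folds: int = 3,
        scoring: str = "roc_auc",
        seed: int = 0,
        fast: bool = False,
    ):
        self.model_id = model_id
        self.grid = grid
        self.inner_folds = inner_folds
        self.scoring = scoring
        self.seed = seed
        self.fast = fast

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        classes = np.unique(y)
        if len(classes) < 2:
            raise UnfittableError("training labels contain a single class")
        base = make_base_estimator(self.model_id, seed=self.seed, fast=self.fast)
        grid = self.grid if self.grid is not None else default_grid(self.model_id, self.fast)
        if _grid_size(grid) <= 1:
            est = clone(base)
            params = {k: v[0] for k, v in (grid or {}).items()}
            est.set_params(**params)
            est.fit(X, y)
            self.best_estimator_ = est
            self.best_params_ = params
        else:
            cv = StratifiedKFold(self.inner_folds, shuffle=True, random_state=self.seed)
            search = GridSearchCV(
                base, grid, scoring=self.scoring, cv=cv, n_jobs=1, refit=True,
                error_score=-np.inf,
            )
            search.fit(X, y)
            self.best_estimator_ = search.best_estimator_
            self.best_params_ = search.best_params_
        self.classes_ = self.best_estimator_.classes_
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.best_estimator_.predict_proba(X)

    def predict(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        return self.best_estimator_.predict(X)


class StackingBinaryClassifier(BaseEstimator, ClassifierMixin):
    """Level-1 unpenalized logistic regression over base-model probabilities.

    ``fit`` consumes a matrix whose columns are the base models' predicted
    remission probabilities (out-of-fold on the training partition in the
    default anti-leakage mode, or resubstitution if chosen — the caller
    decides which probabilities to pass).
    """

    def __init__(self, seed: int = 0):
        self.seed = seed

    def fit(self, X, y):
        X, y = validate_data(self, X, y)
        if len(np.unique(y)) < 2:
            raise UnfittableError("training labels contain a single class")
        # unpenalized logistic meta-model
        self.meta_ = LogisticRegression(C=np.inf, max_iter=1000, random_state=self.seed)
        self.meta_.fit(X, y)
        self.classes_ = self.meta_.classes_
        self.n_base_ = X.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self)
        X = validate_data(self, X, reset=False)
        if X.shape[1] != self.n_base_:
            raise ValueError(
                f"expected {self.n_base_} base-probability columns, got {X.shape[1]}"
            )
        return self.meta_.predict_proba(X)

    def predict(self, X):
        return self.classes_[np.argmax(self.predict_proba(X), axis=1)]
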