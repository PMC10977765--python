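"""Consensus feature selection by rank frequency.

Each of several learners is fitted on many resampled training partitions —
every imputation x CV repeat x fold — and outputs its ``top_k``
most-important features.  A tally over all those lists is kept and the
``keep_n`` most frequent names form the consensus selection.  At the
settings used on real data (M=10 imputations, 5 repeats, 5 folds, 6 models,
top 20) the tally counts 30,000 entries.

Importance measures: absolute coefficient magnitude for penalized
regressions, impurity importance for tree ensembles, and permutation
importance (mean drop in ROC-AUC when one feature is shuffled) for the SVM
and neural network, which expose no built-in measure.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.inspection import permutation_importance as _sk_permutation_importance
from sklearn.metrics import check_scoring

from .impute import ImputedStack
from .models import SELECTION_MODELS, UnknownModelError, make_base_estimator
from .preprocess import standardize_frames

__all__ = [
    "SelectionSettings",
    "ImportanceTally",
    "SelectionResult",
    "rank_features",
    "permutation_importance",
    "consensus_select",
    "ConsensusFeatureSelector",
]


class SelectionConfigError(ValueError):
    pass


@dataclass
class SelectionSettings:
    """Resampling plan and model list of the consensus-selection stage."""

    R: int = 5
    K: int = 5
    models: Sequence[str] = SELECTION_MODELS
    top_k: int = 20
    keep_n: int = 50
    perm_repeats: int = 3
    fast: bool = True

    def __post_init__(self) -> None:
        if not self.models:
            raise SelectionConfigError("model list must not be empty")
        if self.R < 1 or self.K < 2 or self.top_k < 1 or self.keep_n < 1:
            raise SelectionConfigError("invalid selection settings")


@dataclass
class ImportanceTally:
    """feature name -> frequency, accumulated over imputations x repeats x folds x models."""

    counts: dict[str, int]
    provenance: dict

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))

    def expected_total(self) -> int:
        p = self.provenance
        return p["M"] * p["R"] * p["K"] * len(p["models"]) * p["top_k"]


@dataclass
class SelectionResult:
    """Ordered consensus selection plus its full tally."""

    selected: list[str]
    tally: ImportanceTally

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "selected": self.selected,
                    "counts": self.tally.counts,
                    "provenance": self.tally.provenance,
                },
                indent=1,
            )
        )


def permutation_importance(
    fitted_model,
    X: pd.DataFrame,
    y: np.ndarray,
    metric: str = "roc_auc",
    n_repeats: int = 5,
    seed: int = 0,
) -> np.ndarray:
    """Mean metric drop per feature when its values are shuffled.

    Thin, seed-deterministic wrapper: importance(f) = mean over repeats of
    metric(original) - metric(f shuffled).
    """
    if len(np.unique(np.asarray(y))) < 2:
        raise ValueError("metric undefined on single-class labels")
    check_scoring(fitted_model, scoring=metric)
    res = _sk_permutation_importance(
        fitted_model, X, y, scoring=metric, n_repeats=n_repeats, random_state=seed, n_jobs=1
    )
    return res.importances_mean


def rank_features(
    model_id: str,
    X: pd.DataFrame,
    y: np.ndarray,
    top_k: int = 20,
    seed: int = 0,
    perm_repeats: int = 5,
    fast: bool = True,
) -> list[str]:
    """Fit one learner and return its ``top_k`` features by importance.

    Ties break by canonical column order (stable argsort).
    """
    if model_id not in SELECTION_MODELS and model_id != "penalized_logistic":
        raise UnknownModelError(model_id)
    if top_k > X.shape[1]:
        raise SelectionConfigError(
            f"top_k={top_k} exceeds feature count {X.shape[1]}"
        )
    est = make_base_estimator(model_id, seed=seed, fast=fast)
    if model_id == "svm":
        est.set_params(probability=False)  # decision_function suffices for ranking
    est.fit(X.to_numpy(), np.asarray(y))
    if model_id in ("lasso", "ridge", "penalized_logistic"):
        importance = np.abs(est.coef_).ravel()
    elif model_id in ("random_forest", "xgboost"):
        importance = np.asarray(est.feature_importances_, dtype=float)
    else:  # svm, neural_network: no built-in measure
        importance = permutation_importance(
            est, X.to_numpy(), np.asarray(y), n_repeats=perm_repeats, seed=seed
        )
    order = np.argsort(-importance, kind="stable")
    return [X.columns[i] for i in order[:top_k]]


def consensus_select(
    stack: ImputedStack,
    settings: SelectionSettings | None = None,
    seed: int = 0,
) -> SelectionResult:
    """Tally top-ranked features over imputations x repeats x folds x models.

    For every imputation, CV repeat and fold, each model is fitted on the
    fold-training part (continuous features standardized within the fold)
    and its ``top_k`` names are recorded.  The ``keep_n`` most frequent
    names, ties broken by name, form the selection.
    """
    settings = settings or SelectionSettings()
    first = stack.tables[0]
    feats = first.feature_names
    if settings.keep_n > len(feats):
        raise SelectionConfigError("keep_n exceeds feature count")
    continuous = [f.name for f in first.features if f.kind == "continuous"]
    counts: Counter[str] = Counter()
    labels = stack.remission_labels()
    for m, table in enumerate(stack.tables):
        y_all = labels[m].to_numpy()
        for r in range(settings.R):
            rng = np.random.default_rng([seed, m, r])
            perm = rng.permutation(table.n)
            folds = np.array_split(perm, settings.K)
            for k, test_idx in enumerate(folds):
                train_idx = np.setdiff1d(perm, test_idx, assume_unique=True)
                X_tr = table.values.iloc[train_idx]
                y_tr = y_all[train_idx]
                X_tr, _ = standardize_frames(X_tr, None, continuous)
                for model_id in settings.models:
                    fit_seed = int(
                        np.random.SeedSequence([seed, m, r, k]).generate_state(1)[0]
                        % (2**31 - 1)
                    )
                    top = rank_features(
                        model_id,
                        X_tr,
                        y_tr,
                        top_k=settings.top_k,
                        seed=fit_seed,
                        perm_repeats=settings.perm_repeats,
                        fast=settings.fast,
                    )
                    counts.update(top)
    tally = ImportanceTally(
        counts=dict(counts),
        provenance={
            "M": stack.M,
            "R": settings.R,
            "K": settings.K,
            "models": list(settings.models),
            "top_k": settings.top_k,
            "keep_n": settings.keep_n,
            "seed": seed,
        },
    )
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    selected = [name for name, _ in ranked[: settings.keep_n]]
    return SelectionResult(selected=selected, tally=tally)


class ConsensusFeatureSelector(BaseEstimator):
    """Estimator-style wrapper around :func:`consensus_select`.

    ``fit`` consumes an :class:`~remisml.impute.ImputedStack`; the fitted
    attributes are ``selected_features_`` and ``tally_``.
    """

    def __init__(self, settings: SelectionSettings | None = None, seed: int = 0):
        self.settings = settings
        self.seed = seed

    def fit(self, stack: ImputedStack, y=None):
        result = consensus_select(stack, self.settings, seed=self.seed)
        self.selected_features_ = result.selected
        self.tally_ = result.tally
        return self

    def transform(self, stack: ImputedStack) -> ImputedStack:
        return stack.restrict_features(self.selected_features_)
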