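"""Repeated K-fold evaluation with nested hyperparameter search and stacking.

The evaluation scheme is five-repeated four-fold cross-validation: each
repeat partitions the training cohort into four near-equal folds; each fold
in turn is the outer test set while the other three train the base learners,
each tuned by an inner 3-fold grid search.  Two stacking meta-models (over
all six base probabilities, and over penalized-logistic + neural-network
only) sit on top.  External validation refits on the full training study and
predicts the paired test-study imputation.

Predictions are emitted as a long-format table (participant, imputation,
repeat, fold, model, probability, true label, role) that the evaluation and
ROC modules consume.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from .impute import ImputedStack
from .models import (
    MODELING_MODELS,
    NestedSearchClassifier,
    StackingBinaryClassifier,
)
from .select import SelectionSettings, consensus_select

__all__ = [
    "ResamplingPlan",
    "make_plan",
    "fit_base",
    "fit_stack",
    "run_internal_cv",
    "external_validate",
    "STACK_ALL",
    "STACK_PLR_NN",
]

STACK_ALL = "stack_all"
STACK_PLR_NN = "stack_plr_nn"
_PLR_NN = ("penalized_logistic", "neural_network")

PREDICTION_COLUMNS = [
    "participant",
    "imputation",
    "repeat",
    "fold",
    "model",
    "prob",
    "y_true",
    "role",
]


class PlanError(ValueError):
    pass


@dataclass
class ResamplingPlan:
    """Seed-deterministic repeated K-fold partition of n participants.

    ``assignments[r]`` is an integer fold index (0..K-1) per participant for
    repeat r; every repeat's folds partition all participants with sizes
    differing by at most one.
    """

    R: int
    K: int
    inner_folds: int
    assignments: list[np.ndarray]
    seed: int

    def folds(self, r: int) -> list[np.ndarray]:
        a = self.assignments[r]
        return [np.flatnonzero(a == k) for k in range(self.K)]


def make_plan(n: int, R: int = 5, K: int = 4, inner_folds: int = 3, seed: int = 0) -> ResamplingPlan:
    """Build R independent K-fold partitions of n participants."""
    if n < K:
        raise PlanError(f"cannot split n={n} participants into K={K} folds")
    assignments = []
    for r in range(R):
        rng = np.random.default_rng([seed, r])
        perm = rng.permutation(n)
        a = np.empty(n, dtype=int)
        for k, chunk in enumerate(np.array_split(perm, K)):
            a[chunk] = k
        assignments.append(a)
    return ResamplingPlan(R=R, K=K, inner_folds=inner_folds, assignments=assignments, seed=seed)


def fit_base(
    model_id: str,
    X_train: np.ndarray | pd.DataFrame,
    y_train: np.ndarray,
    inner_folds: int = 3,
    grid: dict | None = None,
    seed: int = 0,
    fast: bool = False,
) -> NestedSearchClassifier:
    """Fit one base learner with the inner grid search; returns the estimator."""
    clf = NestedSearchClassifier(
        model_id=model_id, grid=grid, inner_folds=inner_folds, seed=seed, fast=fast
    )
    return clf.fit(np.asarray(X_train), np.asarray(y_train))


def fit_stack(
    base_probs_train: pd.DataFrame,
    labels: np.ndarray,
    variant: str = STACK_ALL,
    seed: int = 0,
) -> tuple[StackingBinaryClassifier, list[str]]:
    """Fit the logistic meta-model on base-model probabilities.

    ``variant`` selects the meta-feature columns: ``stack_all`` uses every
    base model, ``stack_plr_nn`` only penalized logistic regression and the
    neural network.  Returns the fitted meta-model and the column order it
    expects at prediction time.
    """
    if len(base_probs_train) != len(labels):
        raise ValueError("base probabilities and labels are misaligned")
    if variant == STACK_ALL:
        cols = list(base_probs_train.columns)
    elif variant == STACK_PLR_NN:
        cols = [c for c in _PLR_NN if c in base_probs_train.columns]
        if len(cols) != 2:
            raise ValueError(
                "stack_plr_nn needs penalized_logistic and neural_network base columns"
            )
    else:
        raise ValueError(f"unknown stacking variant {variant!r}")
    meta = StackingBinaryClassifier(seed=seed)
    meta.fit(base_probs_train[cols].to_numpy(), np.asarray(labels))
    return meta, cols


def _oof_base_probs(
    models: Sequence[str],
    X: np.ndarray,
    y: np.ndarray,
    inner_folds: int,
    seed: int,
    fast: bool,
    resubstitution: bool,
) -> pd.DataFrame:
    """Base probabilities on the training partition for meta-model training.

    Default anti-leakage mode: out-of-fold via an inner stratified split.
    ``resubstitution=True`` reproduces the optimistic variant in which the
    refitted base models score their own training rows.
    """
    probs = {}
    for model_id in models:
        clf = NestedSearchClassifier(model_id=model_id, inner_folds=inner_folds, seed=seed, fast=fast)
        if resubstitution:
            clf.fit(X, y)
            probs[model_id] = clf.predict_proba(X)[:, 1]
        else:
            cv = StratifiedKFold(inner_folds, shuffle=True, random_state=seed)
            probs[model_id] = cross_val_predict(clf, X, y, cv=cv, method="predict_proba")[:, 1]
    return pd.DataFrame(probs)


def _fit_cell(
    models: Sequence[str],
    stacking: Sequence[str],
    X_tr: np.ndarray,
    y_tr: np.ndarray,
    X_te: np.ndarray,
    inner_folds: int,
    seed: int,
    fast: bool,
    stack_resubstitution: bool,
) -> dict[str, np.ndarray]:
    """Fit bases + stacks on one training partition; return test probabilities."""
    test_probs: dict[str, np.ndarray] = {}
    fitted = {}
    for model_id in models:
        clf = fit_base(model_id, X_tr, y_tr, inner_folds=inner_folds, seed=seed, fast=fast)
        fitted[model_id] = clf
        test_probs[model_id] = clf.predict_proba(X_te)[:, 1]
    if stacking:
        train_base = _oof_base_probs(
            models, X_tr, y_tr, inner_folds, seed, fast, stack_resubstitution
        )
        test_base = pd.DataFrame({m: test_probs[m] for m in models})
        for variant in stacking:
            meta, cols = fit_stack(train_base, y_tr, variant=variant, seed=seed)
            test_probs[variant] = meta.predict_proba(test_base[cols].to_numpy())[:, 1]
    return test_probs


def _standardize_split(table, train_idx, test_idx, feature_names, continuous):
    from .preprocess import standardize_frames

    X = table.values[feature_names]
    X_tr, X_te = standardize_frames(X.iloc[train_idx], X.iloc[test_idx], continuous)
    return X_tr.to_numpy(), X_te.to_numpy()


def run_internal_cv(
    stack: ImputedStack,
    plan: ResamplingPlan,
    models: Sequence[str] = MODELING_MODELS,
    selection: SelectionSettings | list[str] | None = None,
    stacking: Sequence[str] = (STACK_ALL, STACK_PLR_NN),
    leakage_mode: str = "per_fold",
    stack_resubstitution: bool = False,
    fast: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Repeated K-fold evaluation of bases + stacks on an imputed stack.

    ``selection`` may be an explicit feature list, a
    :class:`~remisml.select.SelectionSettings` to run consensus selection, or
    None (use all features).  ``leakage_mode='per_fold'`` reruns the
    consensus selection on each outer-training partition (no test-fold row
    ever influences selection); ``'global'`` selects once on the full stack
    before the CV loop — the optimistic once-per-training-set variant.

    Returns the long-format prediction table with role ``outer_test``.
    """
    if leakage_mode not in ("per_fold", "global"):
        raise ValueError("leakage_mode must be 'per_fold' or 'global'")
    first = stack.tables[0]
    continuous_all = {f.name for f in first.features if f.kind == "continuous"}
    labels = stack.remission_labels()

    def resolve_selection(sub_stack) -> list[str]:
        if selection is None:
            return first.feature_names
        if isinstance(selection, SelectionSettings):
            return consensus_select(sub_stack, selection, seed=seed).selected
        return list(selection)

    global_features = None
    if leakage_mode == "global" or not isinstance(selection, SelectionSettings):
        global_features = resolve_selection(stack)

    rows = []
    part = first.participants
    for r in range(plan.R):
        folds = plan.folds(r)
        for k, test_idx in enumerate(folds):
            train_idx = np.flatnonzero(~np.isin(np.arange(first.n), test_idx))
            if global_features is not None:
                feats = global_features
            else:
                feats = resolve_selection(stack.restrict_participants(part[train_idx]))
            continuous = [f for f in feats if f in continuous_all]
            cell_seed = int(
                np.random.SeedSequence([seed, r, k]).generate_state(1)[0] % (2**31 - 1)
            )
            for m, table in enumerate(stack.tables):
                y = labels[m].to_numpy()
                X_tr, X_te = _standardize_split(table, train_idx, test_idx, feats, continuous)
                probs = _fit_cell(
                    models, stacking, X_tr, y[train_idx], X_te,
                    plan.inner_folds, cell_seed, fast, stack_resubstitution,
                )
                for model_name, p in probs.items():
                    for i, idx in enumerate(test_idx):
                        rows.append(
                            (part[idx], m, r, k, model_name, float(p[i]), y[idx], "outer_test")
                        )
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)


def external_validate(
    train_stack: ImputedStack,
    test_stack: ImputedStack,
    models: Sequence[str] = MODELING_MODELS,
    selection: SelectionSettings | list[str] | None = None,
    stacking: Sequence[str] = (STACK_ALL, STACK_PLR_NN),
    inner_folds: int = 3,
    stack_resubstitution: bool = False,
    fast: bool = False,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit on the full training study, predict the paired test imputation.

    Feature selection runs once on the training stack (never on test rows);
    per imputation m the bases are tuned and refitted on the complete
    training cohort of imputation m and predict the test cohort of the same
    imputation.  Returns predictions with role ``external_test``.
    """
    first_tr = train_stack.tables[0]
    first_te = test_stack.tables[0]
    if [f.name for f in first_tr.features] != [f.name for f in first_te.features]:
        raise ValueError("train and test stacks are not harmonized")
    if train_stack.M != test_stack.M:
        raise ValueError("train and test stacks must have equal M")
    if selection is None:
        feats = first_tr.feature_names
    elif isinstance(selection, SelectionSettings):
        feats = consensus_select(train_stack, selection, seed=seed).selected
    else:
        feats = list(selection)
    continuous = [
        f.name for f in first_tr.features if f.kind == "continuous" and f.name in set(feats)
    ]
    labels_tr = train_stack.remission_labels()
    labels_te = test_stack.remission_labels()

    from .preprocess import standardize_frames

    rows = []
    part_te = first_te.participants
    for m, (t_tr, t_te) in enumerate(zip(train_stack.tables, test_stack.tables)):
        y_tr = labels_tr[m].to_numpy()
        y_te = labels_te[m].to_numpy()
        X_tr, X_te = standardize_frames(
            t_tr.values[feats], t_te.values[feats], continuous
        )
        cell_seed = int(np.random.SeedSequence([seed, m]).generate_state(1)[0] % (2**31 - 1))
        probs = _fit_cell(
            models, stacking, X_tr.to_numpy(), y_tr, X_te.to_numpy(),
            inner_folds, cell_seed, fast, stack_resubstitution,
        )
        for model_name, p in probs.items():
            for i, pid in enumerate(part_te):
                rows.append((pid, m, 0, 0, model_name, float(p[i]), y_te[i], "external_test"))
    return pd.DataFrame(rows, columns=PREDICTION_COLUMNS)
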