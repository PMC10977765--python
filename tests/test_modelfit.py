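import numpy as np
import pandas as pd
import pytest

from remisml.evaluate import auc
from remisml.models import (
    NestedSearchClassifier,
    StackingBinaryClassifier,
    UnfittableError,
    make_base_estimator,
)
from remisml.modelfit import (
    PlanError,
    STACK_ALL,
    STACK_PLR_NN,
    external_validate,
    fit_base,
    fit_stack,
    make_plan,
    run_internal_cv,
)
from remisml.impute import ImputedStack
from remisml.cohort import FeatureMeta

from conftest import manual_cohort


class TestMakePlan:
    def test_four_folds_of_two(self):
        plan = make_plan(8, R=1, K=4, seed=0)
        sizes = sorted(len(f) for f in plan.folds(0))
        assert sizes == [2, 2, 2, 2]

    def test_near_equal_sizes_and_coverage(self):
        plan = make_plan(78, R=5, K=4, seed=1)
        for r in range(5):
            folds = plan.folds(r)
            sizes = sorted(len(f) for f in folds)
            assert sizes == [19, 19, 20, 20]
            assert sorted(np.concatenate(folds)) == list(range(78))

    def test_seed_determinism(self):
        a = make_plan(30, R=2, K=3, seed=9)
        b = make_plan(30, R=2, K=3, seed=9)
        for x, y in zip(a.assignments, b.assignments):
            np.testing.assert_array_equal(x, y)

    def test_repeats_differ(self):
        plan = make_plan(30, R=2, K=3, seed=9)
        assert not np.array_equal(plan.assignments[0], plan.assignments[1])

    def test_too_few_participants(self):
        with pytest.raises(PlanError):
            make_plan(3, K=4)


def _separable(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.r_[np.zeros(n // 2), np.ones(n // 2)].astype(int)
    X = np.c_[y * 4.0 + rng.standard_normal(n) * 0.1, rng.standard_normal(n)]
    return X, y


class TestFitBase:
    def test_separable_data_perfect_training_accuracy(self):
        X, y = _separable()
        clf = fit_base("penalized_logistic", X, y, fast=True, seed=0)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_single_configuration_equals_direct_fit(self):
        X, y = _separable(seed=3)
        grid = {"C": [0.5]}
        clf = fit_base("penalized_logistic", X, y, grid=grid, seed=1, fast=True)
        direct = make_base_estimator("penalized_logistic", seed=1, fast=True)
        direct.set_params(C=0.5).fit(X, y)
        np.testing.assert_allclose(
            clf.predict_proba(X), direct.predict_proba(X), atol=1e-12
        )

    def test_single_class_rejected(self):
        X, _ = _separable()
        with pytest.raises(UnfittableError):
            fit_base("penalized_logistic", X, np.zeros(len(X), dtype=int))

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        clf = NestedSearchClassifier(model_id="svm", seed=3)
        cloned = clone(clf)
        assert cloned.get_params() == clf.get_params()


class TestFitStack:
    def test_identical_bases_preserve_ordering(self):
        rng = np.random.default_rng(0)
        p = rng.random(60)
        y = (rng.random(60) < p).astype(int)
        base = pd.DataFrame({"m1": p, "m2": p, "m3": p})
        meta, cols = fit_stack(base, y, variant=STACK_ALL)
        stacked = meta.predict_proba(base[cols].to_numpy())[:, 1]
        assert auc(y, stacked) == pytest.approx(auc(y, p))

    def test_plr_nn_variant_consumes_two_columns(self):
        rng = np.random.default_rng(1)
        y = rng.integers(0, 2, 50)
        base = pd.DataFrame(
            rng.random((50, 3)),
            columns=["penalized_logistic", "neural_network", "svm"],
        )
        meta, cols = fit_stack(base, y, variant=STACK_PLR_NN)
        assert cols == ["penalized_logistic", "neural_network"]
        assert meta.n_base_ == 2
        with pytest.raises(ValueError):
            meta.predict_proba(rng.random((5, 3)))

    def test_perfect_base_dominates_noise_bases(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, 100)
        base = pd.DataFrame(
            {"good": y + 0.01 * rng.standard_normal(100),
             "noise1": rng.random(100), "noise2": rng.random(100)}
        )
        meta, cols = fit_stack(base, y, variant=STACK_ALL)
        stacked = meta.predict_proba(base[cols].to_numpy())[:, 1]
        assert auc(y, stacked) >= max(auc(y, base["noise1"]), auc(y, base["noise2"]))

    def test_misaligned_rows_rejected(self):
        with pytest.raises(ValueError):
            fit_stack(pd.DataFrame({"a": [0.1, 0.2]}), np.array([1]))


def _stack_for_cv(n=40, p=6, beta=3.0, seed=0, M=1):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.standard_normal((n, p)), columns=[f"f{i}" for i in range(p)])
    logits = beta * X["f0"]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(int)
    feats = [FeatureMeta(c, "continuous") for c in X.columns]
    hdrs = np.where(y == 1, 5.0, 15.0)
    tables = [manual_cohort(X.to_dict("list"), feats, hdrs8=list(hdrs)) for _ in range(M)]
    return ImputedStack(tables)


class TestRunInternalCV:
    def test_every_participant_tested_once_per_repeat(self):
        stack = _stack_for_cv(n=40)
        plan = make_plan(40, R=2, K=4, seed=0)
        preds = run_internal_cv(
            stack, plan, models=("ridge",), selection=None, stacking=(), fast=True, seed=1
        )
        counts = preds.groupby(["repeat", "participant"]).size()
        assert (counts == 1).all()
        assert preds["prob"].between(0, 1).all()

    def test_strong_signal_recovers_high_auc(self):
        stack = _stack_for_cv(n=120, beta=3.0, seed=4)
        plan = make_plan(120, R=1, K=4, seed=2)
        preds = run_internal_cv(
            stack, plan, models=("penalized_logistic",), selection=None,
            stacking=(), fast=True, seed=3,
        )
        assert auc(preds["y_true"].to_numpy(), preds["prob"].to_numpy()) > 0.8

    def test_single_base_stacking_preserves_auc(self):
        """Stacking over one base model is a monotone transform of it."""
        stack = _stack_for_cv(n=60, seed=5)
        plan = make_plan(60, R=1, K=3, seed=0)
        preds = run_internal_cv(
            stack, plan, models=("penalized_logistic",), selection=None,
            stacking=(STACK_ALL,), fast=True, seed=1,
        )
        base = preds[preds["model"] == "penalized_logistic"]
        stacked = preds[preds["model"] == STACK_ALL]
        for (r, k), df_b in base.groupby(["repeat", "fold"]):
            df_s = stacked[(stacked["repeat"] == r) & (stacked["fold"] == k)]
            if df_b["y_true"].nunique() == 2:
                assert auc(df_b["y_true"].to_numpy(), df_b["prob"].to_numpy()) == pytest.approx(
                    auc(df_s["y_true"].to_numpy(), df_s["prob"].to_numpy())
                )

    def test_per_fold_selection_runs_without_touching_test_rows(self):
        """Anti-leakage mode: consensus selection reruns on each
        outer-training partition and the evaluation still covers everyone."""
        from remisml.select import SelectionSettings

        stack = _stack_for_cv(n=60, p=8, beta=3.0, seed=21)
        plan = make_plan(60, R=1, K=3, seed=2)
        settings = SelectionSettings(R=1, K=2, models=("lasso",), top_k=4, keep_n=4)
        preds = run_internal_cv(
            stack, plan, models=("ridge",), selection=settings,
            stacking=(), leakage_mode="per_fold", fast=True, seed=3,
        )
        counts = preds.groupby(["repeat", "participant"]).size()
        assert (counts == 1).all()
        # strong signal still found despite per-fold selection
        assert auc(preds["y_true"].to_numpy(), preds["prob"].to_numpy()) > 0.75

    def test_seed_determinism(self):
        stack = _stack_for_cv(n=40, seed=6)
        plan = make_plan(40, R=1, K=4, seed=1)
        kwargs = dict(models=("random_forest",), selection=None, stacking=(), fast=True, seed=2)
        a = run_internal_cv(stack, plan, **kwargs)
        b = run_internal_cv(stack, plan, **kwargs)
        pd.testing.assert_frame_equal(a, b)


class TestExternalValidate:
    def test_train_equals_test_matches_resubstitution(self):
        stack = _stack_for_cv(n=50, seed=7)
        preds = external_validate(
            stack, stack, models=("ridge",), selection=None, stacking=(), fast=True, seed=1
        )
        table = stack.tables[0]
        from remisml.preprocess import standardize_frames
        X_tr, _ = standardize_frames(table.values, None, list(table.values.columns))
        clf = fit_base(
            "ridge", X_tr.to_numpy(), table.remission_binary.to_numpy(),
            seed=int(np.random.SeedSequence([1, 0]).generate_state(1)[0] % (2**31 - 1)),
            fast=True,
        )
        resub = clf.predict_proba(X_tr.to_numpy())[:, 1]
        np.testing.assert_allclose(preds["prob"].to_numpy(), resub, atol=1e-10)

    def test_schema_mismatch_rejected(self):
        a = _stack_for_cv(n=30, p=4, seed=8)
        b = _stack_for_cv(n=30, p=5, seed=9)
        with pytest.raises(ValueError):
            external_validate(a, b, models=("ridge",))

    def test_unequal_m_rejected(self):
        a = _stack_for_cv(n=30, seed=10, M=2)
        b = _stack_for_cv(n=30, seed=11, M=1)
        with pytest.raises(ValueError):
            external_validate(a, b, models=("ridge",))

    def test_iid_external_close_to_internal(self):
        """Same-distribution external cohort: external AUC within 0.1 of the
        internal CV AUC (fixed seeds, strong signal)."""
        train = _stack_for_cv(n=150, beta=3.0, seed=12)
        test = _stack_for_cv(n=150, beta=3.0, seed=13)
        plan = make_plan(150, R=1, K=4, seed=0)
        pi = run_internal_cv(train, plan, models=("penalized_logistic",),
                             selection=None, stacking=(), fast=True, seed=1)
        pe = external_validate(train, test, models=("penalized_logistic",),
                               selection=None, stacking=(), fast=True, seed=1)
        auc_i = auc(pi["y_true"].to_numpy(), pi["prob"].to_numpy())
        auc_e = auc(pe["y_true"].to_numpy(), pe["prob"].to_numpy())
        assert abs(auc_i - auc_e) < 0.1
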