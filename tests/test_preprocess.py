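import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import spearmanr

from remisml.cohort import FeatureMeta
from remisml.preprocess import (
    HarmonizationError,
    SchemaError,
    apply_filter,
    filter_features,
    harmonize_features,
    prune_correlated_measures,
    standardize,
)

from conftest import manual_cohort


def _imaging_block(measures: dict[str, np.ndarray], regions: int) -> tuple[pd.DataFrame, dict]:
    """Build a participants x (measure, region) frame from per-measure bases."""
    cols, labels = {}, {}
    for m, base in measures.items():
        for r in range(regions):
            name = f"{m}_r{r}"
            cols[name] = base[:, r]
            labels[name] = (m, f"r{r}")
    return pd.DataFrame(cols), labels


class TestPruneCorrelatedMeasures:
    def test_exact_duplicate_keeps_first_in_canonical_order(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal((30, 4))
        frame, labels = _imaging_block({"a_thick": base, "b_copy": base}, 4)
        report = prune_correlated_measures(frame, labels)
        assert all(labels[f][0] == "b_copy" for f in report.dropped)
        assert {labels[f][0] for f in report.retained} == {"a_thick"}

    def test_independent_measures_all_retained(self):
        rng = np.random.default_rng(1)
        frame, labels = _imaging_block(
            {m: rng.standard_normal((500, 5)) for m in ["m1", "m2", "m3"]}, 5
        )
        report = prune_correlated_measures(frame, labels)
        assert report.dropped == {}

    def test_constructed_triplet_keeps_a_and_c(self):
        """avg|rho| A-B high, A-C and B-C low -> keep {A, C} (keep-first)."""
        rng = np.random.default_rng(2)
        base = rng.standard_normal((400, 6))
        near_dup = base + 0.25 * rng.standard_normal((400, 6))  # rho ~ 0.97
        indep = rng.standard_normal((400, 6))
        frame, labels = _imaging_block({"A": base, "B": near_dup, "C": indep}, 6)
        report = prune_correlated_measures(frame, labels)
        kept = {labels[f][0] for f in report.retained}
        assert kept == {"A", "C"}
        assert {labels[f][0] for f in report.dropped} == {"B"}

    def test_region_mismatch_raises(self):
        rng = np.random.default_rng(3)
        frame, labels = _imaging_block({"A": rng.standard_normal((10, 3))}, 3)
        labels["extra"] = ("B", "r9")
        frame["extra"] = rng.standard_normal(10)
        with pytest.raises(SchemaError):
            prune_correlated_measures(frame, labels)

    def test_agrees_with_brute_force_oracle(self):
        """Greedy keep-first matches an independently coded all-pairs
        average-|rho| computation on small random instances."""
        rng = np.random.default_rng(4)
        for trial in range(5):
            k, regions, n = 5, 6, 40
            bases = {}
            shared = rng.standard_normal((n, regions))
            for i in range(k):
                mix = rng.uniform(0, 1)
                bases[f"m{i}"] = mix * shared + (1 - mix) * rng.standard_normal((n, regions))
            frame, labels = _imaging_block(bases, regions)
            report = prune_correlated_measures(frame, labels, threshold=0.7)

            # oracle: explicit pairwise matrix + greedy scan
            measures = sorted(bases)
            avg = {}
            for m1, m2 in itertools.combinations(measures, 2):
                rhos = [
                    abs(spearmanr(bases[m1][:, r], bases[m2][:, r]).statistic)
                    for r in range(regions)
                ]
                avg[(m1, m2)] = avg[(m2, m1)] = np.mean(rhos)
            kept = []
            for m in measures:
                if all(avg[(m, j)] < 0.7 for j in kept):
                    kept.append(m)
            assert {labels[f][0] for f in report.retained} == set(kept)

    def test_idempotent(self):
        rng = np.random.default_rng(5)
        base = rng.standard_normal((50, 4))
        frame, labels = _imaging_block({"A": base, "B": base + 0.1 * rng.standard_normal((50, 4))}, 4)
        first = prune_correlated_measures(frame, labels)
        frame2 = frame[first.retained]
        labels2 = {f: labels[f] for f in first.retained}
        second = prune_correlated_measures(frame2, labels2)
        assert second.dropped == {}
        assert second.retained == first.retained


class TestFilterFeatures:
    def _table(self):
        feats = [
            FeatureMeta("flat", "binary", 0, 1),
            FeatureMeta("sparse", "binary", 0, 1),
            FeatureMeta("holey", "continuous"),
            FeatureMeta("fine", "continuous"),
            FeatureMeta("ok_ord", "ordinal_integer", 0, 2),
        ]
        n = 63
        rng = np.random.default_rng(0)
        vals = {
            "flat": np.ones(n),
            "sparse": np.r_[np.zeros(60), np.ones(3)],
            "holey": np.r_[rng.standard_normal(31), [np.nan] * 32],
            "fine": rng.standard_normal(n),
            "ok_ord": rng.integers(0, 3, n).astype(float),
        }
        # ensure ok_ord has all categories well populated
        vals["ok_ord"][:15] = 0; vals["ok_ord"][15:30] = 1; vals["ok_ord"][30:] = 2
        return manual_cohort(vals, feats)

    def test_reasons_assigned(self):
        report = filter_features(self._table(), missing_threshold=0.2)
        assert report.dropped["flat"] == "single_category"
        assert report.dropped["sparse"] == "small_count"
        assert report.dropped["holey"] == "high_missingness"
        assert set(report.retained) == {"fine", "ok_ord"}

    def test_partition_property(self):
        t = self._table()
        report = filter_features(t)
        assert report.all_features == set(t.feature_names)

    def test_idempotent(self):
        t = self._table()
        first = filter_features(t, missing_threshold=0.2)
        again = filter_features(apply_filter(t, first), missing_threshold=0.2)
        assert again.dropped == {}
        assert set(again.retained) == set(first.retained)


class TestHarmonizeFeatures:
    def test_identity_up_to_order(self, tiny_cohort):
        a, b = harmonize_features(tiny_cohort, tiny_cohort.copy())
        assert a.feature_names == sorted(tiny_cohort.feature_names)
        assert set(a.feature_names) == set(tiny_cohort.feature_names)

    def test_intersection(self):
        fa = [FeatureMeta(n, "continuous") for n in ("x", "y", "z")]
        fb = [FeatureMeta(n, "continuous") for n in ("y", "z", "w")]
        a = manual_cohort({n: [1.0, 2.0] for n in "xyz"}, fa)
        b = manual_cohort({n: [1.0, 2.0] for n in "yzw"}, fb)
        ha, hb = harmonize_features(a, b)
        assert ha.feature_names == hb.feature_names == ["y", "z"]
        assert ha.n == a.n and hb.n == b.n

    def test_symmetric_in_retained_set(self):
        fa = [FeatureMeta(n, "continuous") for n in ("x", "y")]
        fb = [FeatureMeta(n, "continuous") for n in ("y", "w")]
        a = manual_cohort({n: [1.0, 2.0] for n in "xy"}, fa)
        b = manual_cohort({n: [1.0, 2.0] for n in "yw"}, fb)
        ab = harmonize_features(a, b)
        ba = harmonize_features(b, a)
        assert ab[0].feature_names == ba[1].feature_names

    def test_conflicting_bounds_raise(self):
        a = manual_cohort({"q": [0.0, 1.0]}, [FeatureMeta("q", "ordinal_integer", 0, 2)])
        b = manual_cohort({"q": [0.0, 1.0]}, [FeatureMeta("q", "ordinal_integer", 0, 3)])
        with pytest.raises(HarmonizationError):
            harmonize_features(a, b)

    def test_shared_count_fixture(self):
        shared = [f"s{i}" for i in range(20)]
        fa = [FeatureMeta(n, "continuous") for n in shared + ["a_only"]]
        fb = [FeatureMeta(n, "continuous") for n in shared + ["b_only"]]
        a = manual_cohort({n: [0.0, 1.0] for n in shared + ["a_only"]}, fa)
        b = manual_cohort({n: [0.0, 1.0] for n in shared + ["b_only"]}, fb)
        ha, hb = harmonize_features(a, b)
        assert len(ha.feature_names) == len(hb.feature_names) == 20


class TestStandardize:
    def test_population_denominator(self):
        feats = [FeatureMeta("x", "continuous")]
        train = manual_cohort({"x": [1.0, 2.0, 3.0]}, feats)
        out, _, params = standardize(train)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
        np.testing.assert_allclose(out.values["x"].to_numpy(), expected, atol=1e-12)
        assert params.mu["x"] == 2.0
        assert params.sigma["x"] == pytest.approx(np.sqrt(2.0 / 3.0))

    def test_zero_variance_maps_to_zero_everywhere(self):
        feats = [FeatureMeta("x", "continuous")]
        train = manual_cohort({"x": [5.0, 5.0, 5.0]}, feats)
        test = manual_cohort({"x": [7.0, 9.0]}, feats)
        out_tr, out_te, _ = standardize(train, test)
        assert (out_tr.values["x"] == 0).all()
        assert (out_te.values["x"] == 0).all()

    def test_test_value_at_training_mean_is_zero(self):
        feats = [FeatureMeta("x", "continuous")]
        train = manual_cohort({"x": [1.0, 3.0]}, feats)
        test = manual_cohort({"x": [2.0]}, feats)
        _, out_te, _ = standardize(train, test)
        assert out_te.values["x"].iloc[0] == pytest.approx(0.0)

    def test_params_come_from_train_only(self, complete_cohort):
        train = complete_cohort.restrict_participants(complete_cohort.participants[:40])
        test = complete_cohort.restrict_participants(complete_cohort.participants[40:])
        out_tr, out_te, params = standardize(train, test)
        cont = [f.name for f in train.features if f.kind == "continuous"]
        assert np.allclose(out_tr.values[cont].mean(), 0.0, atol=1e-10)
        assert np.allclose(out_tr.values[cont].var(ddof=0), 1.0, atol=1e-10)
        # test columns are generally not centered
        assert not np.allclose(out_te.values[cont].mean(), 0.0, atol=1e-3)

    def test_non_continuous_untouched(self, complete_cohort):
        out, _, _ = standardize(complete_cohort)
        for f in complete_cohort.features:
            if f.kind != "continuous":
                assert out.values[f.name].equals(complete_cohort.values[f.name])
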