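"""Splits, metrics, cross-validation, grouped permutation importance and
the comparison harnesses."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surgdur.cohort import default_spec, generate_cohort
from surgdur.evaluation import (
    REFERENCE_BENCHMARK_MAE,
    FeatureBundle,
    Metrics,
    SplitIndices,
    compute_metrics,
    daily_error_reduction,
    kfold_cv,
    permutation_importance,
    run_ablation,
    run_embedding_comparison,
    scatter_data,
    split_dataset,
)
from surgdur.features import FeatureGroup


class TestSplit:
    def test_study_scale_counts(self):
        s = split_dataset(4526, test_frac=0.15, seed=0)
        assert len(s.test) == 679
        assert len(s.validation) == 679
        assert len(s.train) == 3168

    def test_small_n_arithmetic(self):
        s = split_dataset(20, test_frac=0.15, seed=1)
        assert (len(s.test), len(s.validation), len(s.train)) == (3, 3, 14)

    def test_parts_disjoint_and_exhaustive(self):
        s = split_dataset(101, seed=5)
        all_idx = np.concatenate([s.train, s.validation, s.test])
        assert sorted(all_idx.tolist()) == list(range(101))

    def test_deterministic_for_fixed_seed(self):
        a, b = split_dataset(50, seed=3), split_dataset(50, seed=3)
        assert np.array_equal(a.train, b.train)
        assert np.array_equal(a.test, b.test)

    def test_too_small_raises(self):
        with pytest.raises(ValueError):
            split_dataset(2)

    def test_json_round_trip(self, tmp_path):
        s = split_dataset(30, seed=2)
        s.to_json(tmp_path / "s.json")
        back = SplitIndices.from_json(tmp_path / "s.json")
        assert np.array_equal(back.validation, s.validation)


class TestMetrics:
    def test_perfect_fit(self):
        m = compute_metrics([5, 10, 15], [5, 10, 15])
        assert (m.mae, m.rmse, m.r2) == (0.0, 0.0, 1.0)

    def test_mean_predictor_r2_exactly_zero(self):
        y = np.array([3.0, 7.0, 11.0, 19.0])
        m = compute_metrics(y, np.full(4, y.mean()))
        assert m.r2 == 0.0

    def test_hand_computed_example(self):
        m = compute_metrics([0.0, 2.0], [1.0, 1.0])
        assert (m.mae, m.rmse, m.r2) == (1.0, 1.0, 0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            compute_metrics([1, 2], [1, 2, 3])

    def test_constant_truth_warns_and_reports_nan(self):
        with pytest.warns(RuntimeWarning):
            m = compute_metrics([4.0, 4.0], [3.0, 5.0])
        assert np.isnan(m.r2)

    @settings(max_examples=50, deadline=None)
    @given(st.integers(2, 40), st.integers(0, 2**31 - 1))
    def test_mae_never_exceeds_rmse(self, n, seed):
        r = np.random.default_rng(seed)
        m = compute_metrics(r.normal(size=n) * 30 + 40, r.normal(size=n) * 30 + 40)
        assert m.mae <= m.rmse + 1e-12


class TestDailyReduction:
    def test_reference_benchmark_arithmetic(self):
        """Cumulative daily savings recomputed from the reference MAEs."""
        multi = REFERENCE_BENCHMARK_MAE["multihead_mlp"]
        avg = REFERENCE_BENCHMARK_MAE["average"]
        mdn = REFERENCE_BENCHMARK_MAE["ml_mdn"]
        assert round(daily_error_reduction(avg, multi, 5), 1) == 38.3
        assert round(daily_error_reduction(avg, multi, 8), 1) == 61.4
        assert round(daily_error_reduction(mdn, multi, 5), 1) == 29.4


class TestKFold:
    def test_each_row_tested_exactly_once(self):
        records = list(range(10))
        seen = []

        def run_fold(train, test, seed):
            seen.extend(test)
            y = np.arange(len(test), dtype=float)
            return y, y + 1.0

        df = kfold_cv(records, run_fold, k=5, seed=0)
        assert sorted(seen) == records
        assert (df[df["fold"].isin(range(1, 6))]["n"] == 2).all()

    def test_perfect_oracle_gives_zero_mae_per_fold(self):
        records = [float(i) for i in range(25)]

        def run_fold(train, test, seed):
            y = np.asarray(test, dtype=float)
            return y, y.copy()

        df = kfold_cv(records, run_fold, k=5, seed=1)
        folds = df[df["fold"].isin(range(1, 6))]
        assert (folds["mae"] == 0.0).all()

    def test_aggregate_mean_is_arithmetic_mean_of_folds(self, rng):
        records = list(range(40))

        def run_fold(train, test, seed):
            r = np.random.default_rng(seed)
            y = r.normal(size=len(test))
            return y, y + r.normal(size=len(test))

        df = kfold_cv(records, run_fold, k=5, seed=2)
        folds = df[df["fold"].isin(range(1, 6))]
        agg = df[df["fold"] == "mean"].iloc[0]
        assert agg["mae"] == pytest.approx(folds["mae"].mean(), abs=1e-12)

    def test_k_larger_than_n_raises(self):
        with pytest.raises(ValueError):
            kfold_cv([1, 2], lambda *a: None, k=5)


def _toy_bundle(rng, n=400):
    """y = 10*x1 (group g1); x2 (group g2) is irrelevant; text empty."""
    tab = rng.normal(size=(n, 2))
    y = 40.0 + 10.0 * tab[:, 0]
    layout = [FeatureGroup("g1", 0, 1, "tabular"), FeatureGroup("g2", 1, 2, "tabular")]
    return FeatureBundle(tabular=tab, text=np.zeros((n, 0)), y_std=y, y_min=y,
                         layout=layout)


class TestPermutationImportance:
    def test_relevant_group_dominates_irrelevant(self, rng):
        bundle = _toy_bundle(rng)

        def predict(tab, text):
            return 40.0 + 10.0 * tab[:, 0]

        rep = permutation_importance(predict, bundle, repeats=5, seed=0)
        table = rep.table.set_index("group")
        assert table.loc["g1", "delta_mae"] > 1.0
        assert abs(table.loc["g2", "delta_mae"]) < 1e-12
        assert rep.ranking()[0] == "g1"

    def test_constant_column_group_has_exactly_zero_delta(self, rng):
        bundle = _toy_bundle(rng)
        bundle.tabular[:, 1] = 3.14  # constants are permutation-invariant

        def predict(tab, text):
            return 40.0 + 10.0 * tab[:, 0] + tab[:, 1]

        rep = permutation_importance(predict, bundle, repeats=3, seed=0)
        assert rep.table.set_index("group").loc["g2", "delta_mae"] == 0.0

    def test_unknown_group_raises(self, rng):
        bundle = _toy_bundle(rng)
        with pytest.raises(ValueError, match="nonexistent"):
            permutation_importance(lambda t, x: t[:, 0], bundle, repeats=1,
                                   groups=["nonexistent"])

    def test_model_blind_to_text_scores_zero_on_text_groups(self, small_features):
        _, bundle = small_features

        def predict(tab, text):  # provably ignores the text block
            return 38.0 + 5.0 * tab[:, 0]

        rep = permutation_importance(predict, bundle, repeats=2, seed=1,
                                     groups=["text_prepuce", "text_penile"])
        assert (rep.table["delta_mae"] == 0.0).all()


@pytest.fixture(scope="module")
def harness_cohort():
    return generate_cohort(default_spec(n_cases=260, seed=17))


class TestHarnesses:
    def test_ablation_shape_and_shared_split(self, harness_cohort):
        split = split_dataset(len(harness_cohort.records), seed=0)
        df = run_ablation(harness_cohort.records, split, seed=0, max_epochs=3)
        assert len(df) == 4
        assert {"mae", "rmse", "r2"} <= set(df.columns)
        assert df["split"].nunique() == 1
        assert set(df["model"]) == {"singlehead_tabular", "singlehead_text",
                                    "singlehead_concat", "multihead"}

    def test_embedding_comparison_three_strategies(self, harness_cohort):
        split = split_dataset(len(harness_cohort.records), seed=0)
        df = run_embedding_comparison(harness_cohort.records, split, seed=0,
                                      max_epochs=3)
        assert len(df) == 3
        assert df["split"].nunique() == 1
        assert set(df["model"]) == {"tokenize_lstm", "whole_note_embedding",
                                    "structured_embedding"}
        assert df["n"].nunique() == 1  # identical case sets

    def test_scatter_export_pairs(self):
        df = scatter_data([1.0, 2.0], [1.5, 2.5])
        assert isinstance(df, pd.DataFrame)
        assert list(df.columns) == ["true_min", "predicted_min"]


class TestMetricsContainer:
    def test_as_dict_round_trip(self):
        m = Metrics(mae=1.0, rmse=2.0, r2=0.5, n=10)
        assert m.as_dict() == {"mae": 1.0, "rmse": 2.0, "r2": 0.5, "n": 10}
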