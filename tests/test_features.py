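"""Feature pipeline: parsing, imputation, encodings, plan normalization,
assembly, and the training-only dependence of the fitted schema."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from surgdur.catalog import OTHER_CATEGORY
from surgdur.cohort import default_spec, generate_cohort, messify_plan
from surgdur.features import (
    CohortFeaturizer,
    EncodingSchema,
    Standardizer,
    build_multilabel_vocab,
    consolidate_plans,
    decode_multilabel,
    encode_multilabel,
    fit_weight_bins,
    impute_age,
    impute_weight,
    normalize_plan,
    parse_age,
)


class TestParseAge:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("5 years 3 months", 5.25),
            ("0 years 6 months", 0.5),
            ("2 years", 2.0),
            ("7 months", 7 / 12),
            ("", None),
            (None, None),
            ("unknown", None),
        ],
    )
    def test_conversion(self, text, expected):
        got = parse_age(text)
        if expected is None:
            assert got is None
        else:
            assert got == pytest.approx(expected)


class TestImputation:
    def test_parsed_age_wins_over_extracted(self):
        assert impute_age(5.25, 5.0, 4.0) == 5.25

    def test_extracted_age_fills_parse_failure(self):
        assert impute_age(None, 2.5, 4.0) == 2.5

    def test_training_mean_is_last_resort(self):
        assert impute_age(None, None, 4.0) == 4.0

    def test_weight_bin_mean_replaces_missing(self):
        bins = fit_weight_bins(
            np.array([4.2, 4.8, 9.0]), [16.0, 16.4, 30.0], (5, 140)
        )
        assert bins[4] == pytest.approx(16.2)
        assert impute_weight(None, 4.5, bins, (5, 140)) == pytest.approx(16.2)

    def test_abnormal_weight_treated_as_missing(self):
        bins = {4: 16.2}
        assert impute_weight(300.0, 4.0, bins, (5, 140)) == pytest.approx(16.2)

    def test_plausible_weight_passes_through(self):
        assert impute_weight(20.0, 4.0, {4: 16.2}, (5, 140)) == 20.0

    def test_empty_bin_falls_back_to_nearest(self):
        bins = {2: 13.0, 8: 26.0}
        assert impute_weight(None, 4.0, bins, (5, 140)) == 13.0
        assert impute_weight(None, 6.9, bins, (5, 140)) == 26.0

    def test_no_plausible_weights_raises(self):
        with pytest.raises(ValueError):
            fit_weight_bins(np.array([4.0]), [300.0], (5, 140))


class TestStandardizer:
    def test_center_maps_to_zero(self):
        s = Standardizer.fit([1.0, 2.0, 3.0])
        assert s.mean == 2.0
        assert s.apply(2.0) == 0.0

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4, allow_subnormal=False), min_size=3,
                    max_size=40).filter(lambda xs: max(xs) - min(xs) > 1e-6))
    def test_round_trip_identity(self, xs):
        s = Standardizer.fit(xs)
        back = s.invert(s.apply(xs))
        assert np.allclose(back, xs, atol=1e-9 * max(1.0, np.max(np.abs(xs))))

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            Standardizer.fit([3.0, 3.0, 3.0])


class TestMultilabel:
    def test_min_count_threshold_and_rare_bucket(self):
        lists = [["hydrocele"]] * 100 + [["phimosis"]] * 50 + [["odd"]] * 3
        vocab = build_multilabel_vocab(lists, min_count=10)
        assert vocab == ["hydrocele", "phimosis", "rare type"]

    def test_all_rare_collapses_to_bucket_only(self):
        vocab = build_multilabel_vocab([["a"], ["b"]], min_count=10)
        assert vocab == ["rare type"]

    def test_min_count_one_retains_everything(self):
        vocab = build_multilabel_vocab([["a"], ["b"], ["a"]], min_count=1)
        assert vocab == ["a", "b", "rare type"]

    def test_worked_indicator_examples(self):
        vocab = ["hydrocele", "phimosis", "incomplete testicular descent", "rare type"]
        assert encode_multilabel(["hydrocele"], vocab).tolist() == [1, 0, 0, 0]
        assert encode_multilabel(
            ["hydrocele", "phimosis", "incomplete testicular descent"], vocab
        ).tolist() == [1, 1, 1, 0]

    def test_unseen_label_routes_to_rare_bucket(self):
        vocab = ["hydrocele", "rare type"]
        assert encode_multilabel(["never-seen"], vocab).tolist() == [0, 1]

    def test_empty_labels_encode_all_zero(self):
        assert encode_multilabel([], ["a", "rare type"]).sum() == 0

    @settings(max_examples=25, deadline=None)
    @given(st.sets(st.sampled_from(["a", "b", "c", "d"]), max_size=4))
    def test_encode_decode_round_trip(self, labels):
        vocab = ["a", "b", "c", "d", "rare type"]
        decoded = decode_multilabel(encode_multilabel(sorted(labels), vocab), vocab)
        assert set(decoded) == labels


class TestPlanNormalization:
    def test_side_wording_collapses_to_unilateral(self):
        assert normalize_plan("right-sided orchidopexy") == ["orchidopexy (unilateral)"]
        assert normalize_plan("left orchiopexy") == ["orchidopexy (unilateral)"]

    def test_multi_procedure_bilateral_plan(self):
        got = normalize_plan(
            "bilateral laparoscopic high ligation of the processus vaginalis"
            " + orchidopexy + circumcision"
        )
        assert got == [
            "laparoscopic high ligation of the processus vaginalis (bilateral)",
            "orchidopexy (unilateral)",
            "circumcision",
        ]

    def test_idempotence(self):
        raw = "bilateral orchiopexy, right hydrocelectomy，circumcision (stapler)"
        once = normalize_plan(raw)
        assert normalize_plan(" + ".join(once)) == once

    def test_empty_plan_warns_and_returns_empty(self):
        assert normalize_plan("") == []

    def test_messified_plans_normalize_to_truth(self):
        """Every messy rendering of a canonical plan list round-trips."""
        coh = generate_cohort(default_spec(n_cases=500, seed=23))
        for rec, truth in zip(coh.records, coh.truths):
            assert normalize_plan(rec.plan_raw) == truth.canonical_plan

    def test_delimiter_style_invariance(self):
        plan = ["orchidopexy (bilateral)", "circumcision", "preputioplasty"]
        rng = np.random.default_rng(0)
        for _ in range(20):
            assert normalize_plan(messify_plan(plan, rng)) == plan


class TestConsolidation:
    def test_lesion_excisions_group_together(self):
        assert consolidate_plans(["penile cyst excision"]) == ["penile lesion excision"]
        assert consolidate_plans(["penile nevus excision", "penile scar excision"]) == [
            "penile lesion excision"
        ]

    def test_unmapped_token_goes_to_other(self):
        assert consolidate_plans(["some novel operation"]) == [OTHER_CATEGORY]

    def test_standardized_category_is_fixed_point(self):
        assert consolidate_plans(["circumcision"]) == ["circumcision"]


class TestAssembly:
    def test_blocks_and_layout_agree(self, small_features):
        feat, bundle = small_features
        d_tab = sum(g.width for g in bundle.layout if g.head == "tabular")
        assert bundle.tabular.shape[1] == d_tab
        assert bundle.text.shape[1] == 4 * 256
        assert np.isfinite(bundle.tabular).all() and np.isfinite(bundle.text).all()

    def test_procedure_onehot_rows_sum_to_one(self, small_features):
        feat, bundle = small_features
        g = next(g for g in bundle.layout if g.name == "primary_procedure")
        assert np.all(bundle.tabular[:, g.start:g.stop].sum(axis=1) == 1.0)

    def test_all_narratives_missing_gives_null_text_row(self, small_cohort):
        rates = dict(default_spec().missingness_rates)
        rates.update({f: 1.0 for f in ("prepuce", "testicular", "scrotal", "penile")})
        coh = generate_cohort(default_spec(n_cases=30, seed=3, missingness_rates=rates))
        feat = CohortFeaturizer().fit(coh.records)
        bundle = feat.transform(coh.records)
        assert np.all(bundle.text == 0.0)

    def test_surgeon_configurations_swap_columns(self, small_cohort):
        metrics = CohortFeaturizer(surgeon_config="metrics").fit(small_cohort.records)
        names = CohortFeaturizer(surgeon_config="name").fit(small_cohort.records)
        m_groups = {g.name for g in metrics.schema_.layout}
        n_groups = {g.name for g in names.schema_.layout}
        assert {"surgeon_years", "surgeon_volume"} <= m_groups
        assert "surgeon_name" not in m_groups
        assert "surgeon_name" in n_groups
        assert not {"surgeon_years", "surgeon_volume"} & n_groups

    def test_schema_depends_only_on_training_rows(self, small_cohort):
        train = small_cohort.records[:200]
        a = CohortFeaturizer().fit(train).schema_
        b = CohortFeaturizer().fit(train).schema_
        assert a.to_dict() == b.to_dict()
        assert a.fingerprint() == b.fingerprint()

    def test_schema_serialization_round_trip(self, small_features):
        feat, _ = small_features
        clone = EncodingSchema.from_dict(feat.schema_.to_dict())
        assert clone.fingerprint() == feat.schema_.fingerprint()

    def test_target_standardization_round_trip(self, small_features):
        feat, bundle = small_features
        assert np.allclose(feat.to_minutes(bundle.y_std), bundle.y_min, atol=1e-9)

    def test_log_target_switch(self, small_cohort):
        feat = CohortFeaturizer(log_target=True).fit(small_cohort.records)
        bundle = feat.transform(small_cohort.records)
        assert np.allclose(feat.to_minutes(bundle.y_std), bundle.y_min, atol=1e-6)
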