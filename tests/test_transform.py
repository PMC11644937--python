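import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrsynth.transform import (
    CLIP,
    SIGMA_FLOOR,
    CategoricalColumnMeta,
    ContinuousColumnMeta,
    TableTransformer,
    decode_onehot,
    denormalize_value,
    encode_onehot,
    fit_categorical_meta,
    fit_continuous_meta,
    normalize_value,
)

SINGLE_MODE = ContinuousColumnMeta(
    means=np.array([8.0]), stds=np.array([2.0]), weights=np.array([1.0])
)


class TestFitContinuousMeta:
    def test_constant_column_degenerates_to_single_tight_mode(self):
        meta = fit_continuous_meta([5, 5, 5, 5])
        assert meta.n_modes == 1
        assert meta.means[0] == 5
        assert meta.stds[0] == SIGMA_FLOOR

    def test_recovers_two_well_separated_components(self):
        rng = np.random.default_rng(7)
        x = np.where(
            rng.random(1000) < 0.5, rng.normal(0, 1, 1000), rng.normal(10, 1, 1000)
        )
        meta = fit_continuous_meta(x, max_modes=10, seed=0)
        # match each true component to the nearest fitted mode
        for true_mu, true_w in [(0.0, 0.5), (10.0, 0.5)]:
            i = int(np.argmin(np.abs(meta.means - true_mu)))
            assert abs(meta.means[i] - true_mu) < 0.2
            assert abs(meta.weights[i] - true_w) < 0.05

    def test_weights_sum_to_one(self, cohort_table):
        for name in ["Age", "hA1c.#1", "CACS#2.scor"]:
            meta = fit_continuous_meta(cohort_table.column(name), seed=3)
            assert abs(meta.weights.sum() - 1.0) < 1e-6
            assert np.all(meta.stds >= SIGMA_FLOOR)

    def test_deterministic_given_seed(self, cohort_table):
        x = cohort_table.column("Age")
        a = fit_continuous_meta(x, seed=11)
        b = fit_continuous_meta(x, seed=11)
        np.testing.assert_array_equal(a.means, b.means)
        np.testing.assert_array_equal(a.weights, b.weights)

    def test_empty_and_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="empty column"):
            fit_continuous_meta([])
        with pytest.raises(ValueError, match="non-finite"):
            fit_continuous_meta([1.0, np.inf])


class TestNormalizeValue:
    def test_value_at_mode_mean_maps_to_zero(self):
        v, k, post = normalize_value(8.0, SINGLE_MODE)
        assert (v, k) == (0.0, 0)
        assert abs(post.sum() - 1) < 1e-6

    def test_hand_computed_standardization(self):
        v, k, _ = normalize_value(9.0, SINGLE_MODE)
        assert v == pytest.approx(0.5)

    def test_outlier_clipped_to_099(self):
        v, _, _ = normalize_value(20.0, SINGLE_MODE)
        assert v == CLIP

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            normalize_value(np.nan, SINGLE_MODE)


class TestDenormalizeValue:
    def test_zero_maps_to_mode_mean(self):
        assert denormalize_value(0.0, 0, SINGLE_MODE) == 8.0

    def test_hand_inversion(self):
        assert denormalize_value(0.5, 0, SINGLE_MODE) == pytest.approx(9.0)

    def test_out_of_range_mode_rejected(self):
        with pytest.raises(IndexError):
            denormalize_value(0.0, 1, SINGLE_MODE)

    @given(st.floats(min_value=4.5, max_value=11.5))
    @settings(max_examples=50, deadline=None)
    def test_round_trip_identity_where_unclipped(self, c):
        v, k, _ = normalize_value(c, SINGLE_MODE)
        if abs(v) < CLIP:
            assert denormalize_value(v, k, SINGLE_MODE) == pytest.approx(c, abs=1e-9)


class TestCategoricalCodec:
    def test_vocabulary_is_sorted_unique(self):
        meta = fit_categorical_meta(["b", "a", "b"])
        assert meta.categories == ("a", "b")
        assert meta.n_classes == 2
        assert fit_categorical_meta(["x", "x"]).n_classes == 1
        assert fit_categorical_meta(["p", "q", "r"]).n_classes == 3

    def test_onehot_positions(self):
        meta = CategoricalColumnMeta(("a", "b"))
        np.testing.assert_array_equal(encode_onehot("a", meta), [1, 0])
        np.testing.assert_array_equal(encode_onehot("b", meta), [0, 1])
        with pytest.raises(KeyError, match="unknown category"):
            encode_onehot("z", meta)

    def test_decode_argmax_and_tie_rule(self):
        meta = CategoricalColumnMeta(("a", "b"))
        assert decode_onehot([0, 1], meta) == "b"
        assert decode_onehot([0.5, 0.5], meta) == "a"  # tie -> lowest index
        assert decode_onehot([1, 0], meta, mode="sample", seed=99) == "a"

    def test_decode_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            decode_onehot([1, 0, 0], CategoricalColumnMeta(("a", "b")))


class TestTableTransformer:
    def test_flat_width_formula(self, fitted_transformer):
        tr = fitted_transformer
        expect = sum(
            1 + tr.continuous_meta[c.name].n_modes for c in tr.schema.continuous
        ) + sum(
            tr.categorical_meta[c.name].n_classes for c in tr.schema.categorical
        )
        assert tr.width == expect

    def test_row_count_and_clip_invariant(self, cohort_table, fitted_transformer):
        tt = fitted_transformer.transform(cohort_table)
        assert tt.n == cohort_table.n
        assert np.abs(tt.values).max() <= CLIP
        for post in tt.posteriors:
            np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)
        for oh in tt.onehots:
            np.testing.assert_array_equal(oh.sum(axis=1), 1.0)

    def test_round_trip_on_unclipped_cells(self, cohort_table, fitted_transformer):
        tt = fitted_transformer.transform(cohort_table)
        inv = fitted_transformer.inverse_transform(tt)
        unclipped = np.abs(tt.values) < CLIP
        orig = cohort_table.continuous_matrix()
        back = inv.continuous_matrix()
        assert unclipped.sum() > 0
        np.testing.assert_allclose(back[unclipped], orig[unclipped], atol=1e-9)
        # categorical columns survive exactly
        for c in cohort_table.schema.categorical:
            assert list(inv.column(c.name)) == list(cohort_table.column(c.name))

    def test_empty_table_keeps_width(self, cohort_table, fitted_transformer):
        from ehrsynth.schema import DataTable

        empty = DataTable(schema=cohort_table.schema)
        tt = fitted_transformer.transform(empty)
        assert tt.n == 0
        assert tt.width == fitted_transformer.width

    def test_single_row_hand_built_inverse(self):
        import pandas as pd

        from ehrsynth.schema import ColumnKind, ColumnSpec, DataTable, TableSchema
        from ehrsynth.transform import TransformedTable

        schema = TableSchema(
            (
                ColumnSpec("x", ColumnKind.CONTINUOUS),
                ColumnSpec("c", ColumnKind.CATEGORICAL, ("a", "b")),
            )
        )
        tr = TableTransformer(schema)
        tr.continuous_meta = {"x": SINGLE_MODE}
        tr.categorical_meta = {"c": CategoricalColumnMeta(("a", "b"))}
        tt = TransformedTable(
            values=np.array([[0.5]]),
            modes=np.array([[0]]),
            posteriors=[np.array([[1.0]])],
            onehots=[np.array([[0.0, 1.0]])],
        )
        inv = tr.inverse_transform(tt)
        assert inv.frame.loc[0, "x"] == pytest.approx(9.0)
        assert inv.frame.loc[0, "c"] == "b"

    def test_metadata_json_round_trip(self, fitted_transformer, tmp_path):
        path = tmp_path / "meta.json"
        fitted_transformer.save_json(path)
        back = TableTransformer.load_json(path)
        assert back.schema == fitted_transformer.schema
        for name, meta in fitted_transformer.continuous_meta.items():
            np.testing.assert_allclose(back.continuous_meta[name].means, meta.means)
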