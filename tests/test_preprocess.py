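"""Preprocessing chain: filters, special-value encoding, scaling."""

import numpy as np
import pandas as pd
import pytest

from tearomics import preprocess
from tearomics.preprocess import ContaminantRules

from conftest import make_clinical, make_quant

NAN = np.nan


class TestExcludeSparseLevels:
    def test_single_level1_patient_removed(self):
        quant = make_quant(np.ones((7, 3)))
        clin = make_clinical([1, 2, 2, 3, 3, 4, 4])
        clin2, quant2 = preprocess.exclude_sparse_levels(clin, quant)
        assert set(clin2.levels) == {2, 3, 4}
        assert len(clin2.sample_ids) == 6
        assert quant2.sample_ids == clin2.sample_ids

    def test_identity_when_all_levels_populated(self):
        quant = make_quant(np.ones((6, 2)))
        clin = make_clinical([2, 2, 3, 3, 4, 4])
        clin2, quant2 = preprocess.exclude_sparse_levels(clin, quant)
        assert clin2.sample_ids == clin.sample_ids
        pd.testing.assert_frame_equal(quant2.values, quant.values)

    def test_min_count_above_all_class_sizes_errors(self):
        quant = make_quant(np.ones((4, 2)))
        clin = make_clinical([2, 2, 3, 3])
        with pytest.raises(ValueError):
            preprocess.exclude_sparse_levels(clin, quant, min_count=5)


class TestContaminantFilter:
    def test_keratin_18_kept_other_keratin_removed(self):
        names = ["Keratin, type I cytoskeletal 18", "Keratin, type II cytoskeletal 1",
                 "Dermcidin", "Lysozyme C"]
        quant = make_quant(np.ones((3, 4)), names=names)
        out = preprocess.filter_contaminants(quant)
        assert list(out.names.values) == ["Keratin, type I cytoskeletal 18", "Lysozyme C"]

    def test_both_trypsins_removed(self):
        quant = make_quant(np.ones((3, 2)), names=["Trypsin-1", "Putative trypsin-6"])
        out = preprocess.filter_contaminants(quant)
        assert out.values.shape[1] == 0

    def test_dermacolin_spelling_family_removed(self):
        quant = make_quant(np.ones((2, 2)), names=["Dermacoline-2", "Dermcolin A"])
        assert preprocess.filter_contaminants(quant).values.shape[1] == 0

    def test_no_matches_is_identity(self):
        quant = make_quant(np.ones((3, 2)), names=["Lysozyme C", "Lactotransferrin"])
        out = preprocess.filter_contaminants(quant)
        pd.testing.assert_frame_equal(out.values, quant.values)

    def test_empty_pattern_rejected(self):
        with pytest.raises(ValueError):
            ContaminantRules(remove_name_patterns=())


def test_drop_undetected_removes_only_all_missing_columns():
    quant = make_quant([[1.0, NAN, NAN], [2.0, NAN, 3.0]])
    out = preprocess.drop_undetected(quant)
    assert out.values.shape[1] == 2
    single = make_quant(np.vstack([np.full((232, 1), NAN), [[5.0]]]))
    assert preprocess.drop_undetected(single).values.shape[1] == 1


class TestEncodeSpecialValues:
    def test_zero_then_missing_rewrites(self):
        quant = make_quant([[0.0, NAN, 5.2]])
        out = preprocess.encode_special_values(quant)
        np.testing.assert_array_equal(out.values.to_numpy(), [[1.0, 0.0, 5.2]])

    def test_order_keeps_states_distinguishable(self):
        # one inference zero, one non-detection in the same column
        quant = make_quant([[0.0], [NAN], [7.0]])
        out = preprocess.encode_special_values(quant).values.to_numpy().ravel()
        assert set(out) == {1.0, 0.0, 7.0}

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            preprocess.encode_special_values(make_quant([[-1.0]]))


class TestLogStandardize:
    def test_standardized_moments(self):
        rng = np.random.default_rng(2)
        quant = make_quant(np.exp(rng.normal(3, 1, size=(50, 4))))
        mat = preprocess.log_standardize(quant)
        arr = mat.to_numpy()
        assert np.abs(arr.mean(axis=0)).max() < 1e-8
        assert np.abs(arr.std(axis=0) - 1).max() < 1e-8

    def test_constant_column_maps_to_zeros(self):
        quant = make_quant(np.column_stack([np.full(5, 7.0), np.arange(5) + 1.0]))
        mat = preprocess.log_standardize(quant)
        np.testing.assert_array_equal(mat.to_numpy()[:, 0], np.zeros(5))
        assert mat.transform_params.iloc[0]["sd"] == 0.0

    def test_missing_values_rejected(self):
        with pytest.raises(ValueError):
            preprocess.log_standardize(make_quant([[NAN, 1.0]]))


def test_pipeline_equals_stepwise_application(small_cohort):
    _, quant, clinical = small_cohort
    clin_a, matrix_a, _ = preprocess.preprocess_pipeline(clinical, quant)
    clin_b, q = preprocess.exclude_sparse_levels(clinical, quant)
    q = preprocess.filter_contaminants(q)
    q = preprocess.drop_undetected(q)
    q = preprocess.encode_special_values(q)
    matrix_b = preprocess.log_standardize(q)
    assert clin_a.sample_ids == clin_b.sample_ids
    pd.testing.assert_frame_equal(matrix_a.values, matrix_b.values)


def test_column_count_never_increases(small_cohort):
    _, quant, clinical = small_cohort
    _, _, report = preprocess.preprocess_pipeline(clinical, quant)
    shapes = list(report.stage_shapes.values())
    cols = [s[1] for s in shapes]
    assert all(a >= b for a, b in zip(cols[:-1], cols[1:]))


def test_transform_round_trip(small_cohort):
    """Stored params re-applied to the same raw data reproduce the matrix."""
    _, quant, clinical = small_cohort
    _, matrix, _ = preprocess.preprocess_pipeline(clinical, quant)
    q = preprocess.exclude_sparse_levels(clinical, quant)[1]
    q = preprocess.encode_special_values(
        preprocess.drop_undetected(preprocess.filter_contaminants(q))
    )
    redo = preprocess.apply_transform(matrix.transform_params, q)
    np.testing.assert_array_equal(redo.to_numpy(), matrix.to_numpy())
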