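"""Uncertainty weighting: grouping, reweighting equations, rankings."""

import numpy as np
import pytest

from tearomics.attribution import AttributionSet
from tearomics.weighting import (
    BORDERLINE,
    CONFIDENT,
    FeatureRanking,
    NEGATIVE,
    POSITIVE,
    aggregate_importance,
    compare_rankings,
    group_predictions,
    weight_attributions,
    weight_value,
)


def make_attr(values, class_labels=(0, 1)):
    values = np.asarray(values, dtype=float)
    n, c, p = values.shape
    return AttributionSet(
        values=values,
        base_values=np.zeros(c),
        feature_accessions=[f"A{j}" for j in range(p)],
        class_labels=np.asarray(class_labels),
        sample_ids=[f"S{i}" for i in range(n)],
    )


class TestGrouping:
    def test_confident_correct_is_positive(self):
        recs = group_predictions([3], [0.8], true_labels=[3])
        assert recs[0].group == POSITIVE

    def test_confident_wrong_is_negative(self):
        recs = group_predictions([4], [0.7], true_labels=[3])
        assert recs[0].group == NEGATIVE

    def test_probability_exactly_at_threshold_is_borderline(self):
        for true in (3, 4):
            recs = group_predictions([3], [0.6], true_labels=[true])
            assert recs[0].group == BORDERLINE

    def test_without_truth_only_confident_or_borderline(self):
        recs = group_predictions([3, 4], [0.9, 0.5])
        assert [r.group for r in recs] == [CONFIDENT, BORDERLINE]

    def test_misaligned_lengths_rejected(self):
        with pytest.raises(ValueError):
            group_predictions([3, 4], [0.9])
        with pytest.raises(ValueError):
            group_predictions([3], [0.9], true_labels=[3, 4])

    def test_invalid_tau_rejected(self):
        with pytest.raises(ValueError):
            group_predictions([3], [0.9], true_labels=[3], tau=0.0)


class TestWeightValue:
    def test_positive_upweight(self):
        assert weight_value(0.5, 0.8, POSITIVE) == pytest.approx(2.5, abs=1e-12)

    def test_negative_downweight(self):
        assert weight_value(0.5, 0.8, NEGATIVE) == pytest.approx(0.1, abs=1e-12)

    def test_borderline_unchanged(self):
        assert weight_value(-0.3, 0.55, BORDERLINE) == -0.3

    def test_probability_clipping_bounds_the_factor(self):
        assert np.isfinite(weight_value(1.0, 1.0, POSITIVE))
        assert weight_value(1.0, 1.0, POSITIVE) == pytest.approx(1e6, rel=1e-6)

    def test_factor_monotone_in_probability(self):
        ps = np.linspace(0.61, 0.999, 50)
        up = [weight_value(1.0, p, POSITIVE) for p in ps]
        down = [weight_value(1.0, p, NEGATIVE) for p in ps]
        assert all(a < b for a, b in zip(up[:-1], up[1:]))
        assert all(a > b for a, b in zip(down[:-1], down[1:]))


class TestWeightAttributions:
    def test_multiclass_correct_per_class_weighting(self):
        attr = make_attr(np.full((1, 2, 1), 0.2))
        proba = np.array([[0.1, 0.9]])
        recs = group_predictions([1], [0.9], true_labels=[1], sample_ids=["S0"])
        w = weight_attributions(attr, recs, proba, mode="incl_bl")
        assert w.values[0, 1, 0] == pytest.approx(2.0)
        assert w.values[0, 0, 0] == pytest.approx(0.2 * 0.9)

    def test_other_class_uses_its_own_probability(self):
        attr = make_attr(np.full((1, 3, 1), 0.2), class_labels=(2, 3, 4))
        proba = np.array([[0.05, 0.9, 0.05]])
        recs = group_predictions([3], [0.9], true_labels=[3], sample_ids=["S0"])
        w = weight_attributions(attr, recs, proba, mode="incl_bl")
        assert w.values[0, 1, 0] == pytest.approx(0.2 / 0.1)
        assert w.values[0, 0, 0] == pytest.approx(0.2 * 0.95)
        assert w.values[0, 2, 0] == pytest.approx(0.2 * 0.95)

    def test_incorrect_prediction_upweights_true_class(self):
        attr = make_attr(np.full((1, 3, 1), 1.0), class_labels=(2, 3, 4))
        proba = np.array([[0.7, 0.2, 0.1]])  # predicts 2, truth is 3
        recs = group_predictions([2], [0.7], true_labels=[3], sample_ids=["S0"])
        w = weight_attributions(attr, recs, proba, mode="incl_bl")
        assert w.values[0, 1, 0] == pytest.approx(1.0 / 0.8)  # true class 3, p=0.2
        assert w.values[0, 0, 0] == pytest.approx(0.3)  # predicted-but-wrong class
        assert w.values[0, 2, 0] == pytest.approx(0.9)

    def test_contracts_on_randomized_tensors(self):
        rng = np.random.default_rng(12)
        n, c, p = 40, 3, 6
        attr = make_attr(rng.normal(size=(n, c, p)), class_labels=(2, 3, 4))
        proba = rng.dirichlet(np.ones(c) * 0.5, size=n)
        pred_idx = proba.argmax(axis=1)
        pred = np.array([2, 3, 4])[pred_idx]
        p_pred = proba[np.arange(n), pred_idx]
        truth = np.array([2, 3, 4])[rng.integers(0, 3, size=n)]
        recs = group_predictions(pred, p_pred, true_labels=truth)
        w = weight_attributions(attr, recs, proba, mode="incl_bl")
        tau = 0.6
        for i, r in enumerate(recs):
            for ci, cl in enumerate((2, 3, 4)):
                orig = attr.values[i, ci, :]
                new = w.values[i, ci, :]
                # sign is never flipped
                assert np.all(np.sign(new) == np.sign(orig))
                if r.group == BORDERLINE:
                    np.testing.assert_array_equal(new, orig)
                elif r.group == POSITIVE and cl == r.predicted_label:
                    assert np.all(np.abs(new) >= np.abs(orig) / (1 - tau) - 1e-12)
                elif r.group == NEGATIVE and cl != r.true_label and proba[i, ci] > tau:
                    assert np.all(np.abs(new) <= (1 - tau) * np.abs(orig) + 1e-12)

    def test_excl_bl_drops_borderline_and_keeps_values(self):
        rng = np.random.default_rng(13)
        attr = make_attr(rng.normal(size=(4, 2, 3)))
        proba = np.array([[0.1, 0.9], [0.45, 0.55], [0.2, 0.8], [0.7, 0.3]])
        pred = proba.argmax(axis=1)
        p_pred = proba.max(axis=1)
        recs = group_predictions(pred, p_pred)  # no ground truth needed
        w = weight_attributions(attr, recs, proba, mode="excl_bl")
        assert w.sample_ids == ["S0", "S2", "S3"]
        np.testing.assert_array_equal(w.values, attr.values[[0, 2, 3]])

    def test_incl_bl_without_truth_rejected(self):
        attr = make_attr(np.zeros((1, 2, 1)))
        recs = group_predictions([1], [0.9])
        with pytest.raises(ValueError):
            weight_attributions(attr, recs, np.array([[0.1, 0.9]]), mode="incl_bl")

    def test_all_borderline_excl_rejected(self):
        attr = make_attr(np.zeros((1, 2, 1)))
        recs = group_predictions([1], [0.5], true_labels=[1])
        with pytest.raises(ValueError):
            weight_attributions(attr, recs, np.array([[0.5, 0.5]]), mode="excl_bl")


class TestAggregationAndComparison:
    def test_absolute_sum_ranking(self):
        attr = make_attr(np.array([[[2.0, -3.0]], [[0.0, 0.0]]])[:, :, :].reshape(2, 1, 2),
                         class_labels=(1,))
        ranking = aggregate_importance(attr)
        assert [a for a, _ in ranking.entries] == ["A1", "A0"]

    def test_signed_mode_can_differ_from_absolute(self):
        values = np.array([[[1.0, 2.0]], [[1.0, -2.0]]])  # A0 sums 2, A1 cancels
        attr = make_attr(values, class_labels=(1,))
        assert aggregate_importance(attr, signed=True).top(1) == ["A0"]
        assert aggregate_importance(attr, signed=False).top(1) == ["A1"]

    def test_tau_one_incl_bl_ranking_equals_unweighted(self):
        rng = np.random.default_rng(14)
        attr = make_attr(rng.normal(size=(10, 2, 5)))
        proba = rng.dirichlet([1, 1], size=10)
        pred = proba.argmax(axis=1)
        recs = group_predictions(pred, proba.max(axis=1), true_labels=pred, tau=1.0)
        w = weight_attributions(attr, recs, proba, mode="incl_bl")
        np.testing.assert_array_equal(w.values, attr.values)
        assert aggregate_importance(w).entries == aggregate_importance(attr).entries

    def test_no_borderline_excl_ranking_equals_unweighted(self):
        rng = np.random.default_rng(15)
        attr = make_attr(rng.normal(size=(6, 2, 4)))
        proba = np.column_stack([np.full(6, 0.05), np.full(6, 0.95)])
        recs = group_predictions(np.ones(6, dtype=int), proba[:, 1])
        w = weight_attributions(attr, recs, proba, mode="excl_bl")
        assert aggregate_importance(w).entries == aggregate_importance(attr).entries

    def test_empty_retained_rejected(self):
        attr = make_attr(np.zeros((0, 2, 3)))
        with pytest.raises(ValueError):
            aggregate_importance(attr)

    def test_identical_rankings_no_new_entries(self):
        r = FeatureRanking([(f"A{i}", 15.0 - i) for i in range(15)])
        cmp = compare_rankings(r, r, k=15)
        assert cmp.new_in_b == []

    def test_single_substitution_flagged(self):
        a = FeatureRanking([(f"A{i}", 20.0 - i) for i in range(16)])
        entries = [(acc, s) for acc, s in a.entries[:14]] + [("ZZZ", 1.0), a.entries[14]]
        b = FeatureRanking(entries)
        cmp = compare_rankings(a, b, k=15)
        assert cmp.new_in_b == ["ZZZ"]

    def test_reversed_ranking_shift_pattern(self):
        a = FeatureRanking([(f"A{i:02d}", 15.0 - i) for i in range(15)])
        b = FeatureRanking(list(reversed([(acc, 15.0 - s) for acc, s in a.entries])))
        cmp = compare_rankings(a, b, k=15)
        mags = sorted(cmp.shift_magnitudes().values(), reverse=True)
        assert mags == [14, 14, 12, 12, 10, 10, 8, 8, 6, 6, 4, 4, 2, 2, 0]
        assert cmp.new_in_b == []

    def test_k_larger_than_ranking_rejected(self):
        r = FeatureRanking([("A", 1.0)])
        with pytest.raises(ValueError):
            compare_rankings(r, r, k=2)

    def test_ties_broken_lexicographically(self):
        attr = make_attr(np.ones((1, 1, 3)), class_labels=(1,))
        ranking = aggregate_importance(attr)
        assert [a for a, _ in ranking.entries] == ["A0", "A1", "A2"]
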