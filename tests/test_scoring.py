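"""Unit and property tests for the composite-endpoint scorer."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from topicscep import (
    COMPONENT_COLS,
    PreferenceWeights,
    aggregate_components,
    cantril_validate,
    index_cep,
    prorate_component,
    raw_cep,
    reverse_code,
    score_cep,
)
from topicscep.scoring import (
    FUNCTIONAL_COLS,
    ITEM_COLS,
    MORBIDITY_COLS,
    ItemValidationError,
    flip_levels,
)

from conftest import make_record


class TestReverseCoding:
    def test_best_state_orients_to_zero(self, scheme, best_record):
        oriented = reverse_code(best_record, scheme)
        assert (oriented.iloc[0] == 0).all()

    def test_worst_state_orients_to_item_maxima(self, scheme, worst_record):
        oriented = reverse_code(worst_record, scheme)
        expected = {c: scheme.items[c].oriented_max for c in ITEM_COLS}
        assert oriented.iloc[0].to_dict() == expected

    def test_five_level_social_functioning_worst_maps_to_four(self, scheme, best_record):
        rec = best_record.copy()
        rec["social_functioning"] = 1  # interference "all of the time"
        assert reverse_code(rec, scheme).loc[0, "social_functioning"] == 4

    @given(st.integers(min_value=2, max_value=7))
    def test_flip_is_involution_on_every_level_set(self, n_levels):
        levels = np.arange(n_levels)
        assert np.array_equal(flip_levels(flip_levels(levels, n_levels), n_levels), levels)

    def test_missingness_is_preserved(self, scheme, best_record):
        rec = best_record.copy()
        rec.loc[0, "emo_01"] = np.nan
        assert np.isnan(reverse_code(rec, scheme).loc[0, "emo_01"])

    def test_out_of_range_level_names_respondent_and_item(self, scheme, best_record):
        rec = best_record.copy()
        rec.loc[0, "pain"] = 4
        with pytest.raises(ItemValidationError, match="pain"):
            reverse_code(rec, scheme)


class TestProRating:
    def test_worked_example(self):
        assert prorate_component(6, 12, 15) == 7.5

    @given(st.integers(min_value=1, max_value=20), st.integers(min_value=0, max_value=100))
    def test_identity_when_fully_answered(self, n, total):
        assert prorate_component(total, n, n) == pytest.approx(total)

    def test_hand_arithmetic(self):
        assert prorate_component(3, 4, 16) == pytest.approx(12.0)

    @given(
        st.floats(min_value=0, max_value=50, allow_nan=False),
        st.integers(min_value=1, max_value=14),
    )
    def test_scale_equivariance(self, s, n_answered):
        one = prorate_component(s, n_answered, 15)
        two = prorate_component(2 * s, n_answered, 15)
        assert two == pytest.approx(2 * one)

    def test_zero_answered_not_proratable(self):
        with pytest.raises(ValueError, match="pro-ratable"):
            prorate_component(0, 0, 15)


class TestAggregation:
    def test_complete_best_record_gives_all_zero_components(self, scheme, policy, best_record):
        comps = aggregate_components(reverse_code(best_record, scheme), policy, scheme)
        assert comps.loc[0, "scoreable"]
        assert (comps.loc[0, COMPONENT_COLS] == 0).all()

    def test_functional_worked_example_prorates_to_7_5(self, scheme, policy, best_record):
        rec = best_record.copy()
        # 12 answered items summing to 6 limitations, 3 missing
        rec.loc[0, FUNCTIONAL_COLS[:6]] = 1
        rec.loc[0, FUNCTIONAL_COLS[12:]] = np.nan
        comps = aggregate_components(reverse_code(rec, scheme), policy, scheme)
        assert comps.loc[0, "functional_limitations"] == pytest.approx(7.5)
        assert comps.loc[0, "prorated_functional_limitations"]
        assert comps.loc[0, "scoreable"]

    def test_five_missing_morbidities_is_not_scoreable(self, scheme, policy, best_record):
        rec = best_record.copy()
        rec.loc[0, MORBIDITY_COLS[:5]] = np.nan
        comps = aggregate_components(reverse_code(rec, scheme), policy, scheme)
        assert not comps.loc[0, "scoreable"]
        assert comps.loc[0, COMPONENT_COLS].isna().all()

    def test_missing_single_item_is_not_scoreable(self, scheme, policy, best_record):
        rec = best_record.copy()
        rec.loc[0, "self_perceived_health"] = np.nan
        comps = aggregate_components(reverse_code(rec, scheme), policy, scheme)
        assert not comps.loc[0, "scoreable"]


class TestRawScore:
    def test_all_zero_components_hit_the_intercept(self, weights):
        assert raw_cep({c: 0 for c in COMPONENT_COLS}, weights) == pytest.approx(9.00)

    def test_hand_evaluated_linear_formula(self, weights):
        comps = dict(
            zip(COMPONENT_COLS, [2, 1, 5, 1, 0, 1, 2, 1])
        )  # 9 - .36 - .12 - .15 - .03 - 0 - .01 - .34 - .02
        assert raw_cep(comps, weights) == pytest.approx(7.97)

    def test_component_maxima_reach_raw_min(self, weights):
        comps = dict(weights.component_maxima)
        assert raw_cep(comps, weights) == pytest.approx(weights.raw_min)

    def test_worsening_any_component_strictly_lowers_the_score(self, weights):
        base = {c: 1 for c in COMPONENT_COLS}
        r0 = raw_cep(base, weights)
        for c in COMPONENT_COLS:
            worse = dict(base, **{c: 2})
            assert raw_cep(worse, weights) < r0
            assert index_cep(raw_cep(worse, weights), weights) < index_cep(r0, weights)


class TestIndexTransform:
    @pytest.mark.parametrize("anchor,expected", [("raw_max", 10.0), ("raw_min", 0.0)])
    def test_anchors(self, weights, anchor, expected):
        assert index_cep(getattr(weights, anchor), weights) == pytest.approx(expected)

    def test_midpoint_maps_to_five(self, weights):
        mid = (weights.raw_min + weights.raw_max) / 2
        assert index_cep(mid, weights) == pytest.approx(5.0)

    def test_raw_outside_range_signals_mismatch(self, weights):
        with pytest.raises(ValueError, match="inconsistent"):
            index_cep(weights.raw_max + 0.5, weights)


class TestFullScoring:
    def test_best_possible_record_scores_ten(self, scheme, policy, weights, best_record):
        res = score_cep(best_record, scheme, policy, weights)
        assert res.loc[0, "indexed_cep"] == pytest.approx(10.0)

    def test_worst_possible_record_scores_zero(self, scheme, policy, weights, worst_record):
        res = score_cep(worst_record, scheme, policy, weights)
        assert res.loc[0, "indexed_cep"] == pytest.approx(0.0)

    def test_prorated_worked_example_full_path(self, scheme, policy, weights, best_record):
        rec = best_record.copy()
        rec.loc[0, FUNCTIONAL_COLS[:6]] = 1
        rec.loc[0, FUNCTIONAL_COLS[12:]] = np.nan
        res = score_cep(rec, scheme, policy, weights)
        raw = 9.00 - 0.12 * 7.5
        assert res.loc[0, "raw_cep"] == pytest.approx(raw)
        expected_index = (raw - weights.raw_min) / weights.raw_range * 10
        assert res.loc[0, "indexed_cep"] == pytest.approx(expected_index)

    @settings(max_examples=150, deadline=None)
    @given(st.data())
    def test_indexed_score_bounded_on_full_item_lattice(
        self, scheme, policy, weights, data
    ):
        row = {
            col: data.draw(
                st.integers(scheme.items[col].native_min, scheme.items[col].native_max),
                label=col,
            )
            for col in ITEM_COLS
        }
        res = score_cep(pd.DataFrame([row]), scheme, policy, weights)
        assert 0.0 <= res.loc[0, "indexed_cep"] <= 10.0


class TestCantril:
    @pytest.mark.parametrize("value,expected", [(7, 7.0), (0, 0.0), (10, 10.0)])
    def test_valid_values_pass_through(self, value, expected):
        assert cantril_validate(value) == expected

    def test_missing_stays_missing(self):
        assert np.isnan(cantril_validate(np.nan))

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            cantril_validate(11)


def test_weight_derived_quantities_follow_the_scheme(scheme):
    w = PreferenceWeights.for_scheme(scheme)
    assert w.raw_max == pytest.approx(9.00)
    assert w.raw_min == pytest.approx(2.25)
    assert w.raw_range == pytest.approx(6.75)


def test_custom_scheme_changes_raw_range_consistently(scheme):
    from topicscep import ItemSpec

    items = dict(scheme.items)
    for c in ["emo_01", "emo_02", "emo_03", "emo_04", "emo_05"]:
        spec = items[c]
        items[c] = ItemSpec(1, 5, higher_is_better=spec.higher_is_better)
    from topicscep import CodingScheme

    alt = CodingScheme(items=items)
    w = PreferenceWeights.for_scheme(alt)
    # emotional maximum drops from 25 to 20, freeing 5 * 0.03 raw points
    assert w.raw_min == pytest.approx(2.25 + 0.15)
    best = make_record(alt, "best")
    from topicscep import score_cep as sc

    assert sc(best, alt, None, w).loc[0, "indexed_cep"] == pytest.approx(10.0)
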