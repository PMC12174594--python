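"""Trend classification, confusion tables, and exact binomial CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octeval.reference_tables import (REFERENCE_TREND_TABLES,
                                      qualified_percentage,
                                      summarize_reference_tables)
from octeval.trends import (DECREASE, INCREASE, NO_CHANGE, ConfusionTable,
                            TrendRule, binary_metrics, build_trend_table,
                            classify_presence, classify_trend,
                            clopper_pearson, table_accuracy)


class TestClassifyTrend:
    def test_fifteen_percent_rise_is_increase(self):
        assert classify_trend(100, 115).value == INCREASE

    def test_both_zero_fluid_is_no_change_without_flag(self):
        label = classify_trend(0, 0, is_fluid=True)
        assert label.value == NO_CHANGE
        assert not label.adjudication_needed

    def test_tie_zone_flags_adjudication(self):
        label = classify_trend(100, 105)
        assert label.value == NO_CHANGE
        assert label.adjudication_needed

    def test_thresholds_are_asymmetric_as_specified(self):
        # increase: post > pre * 1.1; decrease: post < pre / 1.1
        assert classify_trend(100, 110.0).adjudication_needed
        assert classify_trend(100, 110.1).value == INCREASE
        assert classify_trend(100, 91.0).adjudication_needed
        assert classify_trend(100, 90.0).value == DECREASE

    def test_fluid_appearing_from_zero_is_increase(self):
        assert classify_trend(0, 5, is_fluid=True).value == INCREASE

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            classify_trend(-1, 5)

    @settings(deadline=None, max_examples=200)
    @given(pre=st.floats(0, 1e6), post=st.floats(0, 1e6),
           k=st.floats(1e-3, 1e3))
    def test_scale_invariance(self, pre, post, k):
        a = classify_trend(pre, post)
        b = classify_trend(k * pre, k * post)
        assert a.value == b.value

    @settings(deadline=None, max_examples=200)
    @given(pre=st.floats(0, 1e6), post=st.floats(0, 1e6))
    def test_every_pair_gets_exactly_one_label(self, pre, post):
        label = classify_trend(pre, post)
        assert label.value in (DECREASE, NO_CHANGE, INCREASE)


class TestClassifyPresence:
    @pytest.mark.parametrize("area,min_area,expected", [
        (0, 0, False), (1, 0, True), (5, 5, False), (5.01, 5, True)])
    def test_strict_threshold(self, area, min_area, expected):
        assert classify_presence(area, min_area) is expected


class TestConfusionTable:
    def test_reference_crt_table_margins(self):
        table = REFERENCE_TREND_TABLES["crt_trend"]
        assert table.row_margins.tolist() == [27, 10]
        assert table.col_margins.tolist() == [30, 7]
        assert table.total == 37

    def test_build_from_pairs_round_trips(self):
        pairs = ([(DECREASE, DECREASE)] * 23 + [(DECREASE, INCREASE)] * 4
                 + [(INCREASE, DECREASE)] * 7 + [(INCREASE, INCREASE)] * 3)
        table = build_trend_table(pairs, (DECREASE, INCREASE))
        assert np.array_equal(table.counts,
                              REFERENCE_TREND_TABLES["crt_trend"].counts)

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError):
            build_trend_table([], (DECREASE, INCREASE))

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            build_trend_table([("sideways", DECREASE)], (DECREASE, INCREASE))

    def test_diagonal_table_has_unit_accuracy(self):
        pairs = [(DECREASE, DECREASE)] * 5 + [(INCREASE, INCREASE)] * 2
        assert table_accuracy(
            build_trend_table(pairs, (DECREASE, INCREASE))) == 1.0


class TestTableAccuracy:
    def test_crt_trend_accuracy(self):
        acc = table_accuracy(REFERENCE_TREND_TABLES["crt_trend"])
        assert acc == pytest.approx(26 / 37)
        assert round(acc, 2) == 0.70

    def test_srf_trend_accuracy(self):
        acc = table_accuracy(REFERENCE_TREND_TABLES["srf_trend"])
        assert acc == pytest.approx(34 / 37)
        assert round(acc, 2) == 0.92

    def test_accuracy_bounds(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 10, size=(3, 3))
            if counts.sum() == 0:
                continue
            table = ConfusionTable(counts, ("a", "b", "c"), ("a", "b", "c"))
            acc = table_accuracy(table)
            assert 0.0 <= acc <= 1.0
            off_diag = counts.sum() - np.trace(counts)
            assert (acc == 1.0) == (off_diag == 0)


class TestBinaryMetrics:
    def test_srf_presence_metrics(self):
        bm = binary_metrics(REFERENCE_TREND_TABLES["srf_presence"], "present")
        assert bm.accuracy == pytest.approx(32 / 37)
        assert bm.sensitivity == 0.0
        assert bm.specificity == pytest.approx(32 / 33)
        lo, hi = bm.ci["sensitivity"]
        assert lo == 0.0
        assert round(hi, 2) == 0.60

    def test_irc_presence_metrics(self):
        bm = binary_metrics(REFERENCE_TREND_TABLES["irc_presence"], "present")
        assert bm.accuracy == pytest.approx(24 / 37)
        assert bm.sensitivity == pytest.approx(5 / 15)
        assert bm.specificity == pytest.approx(19 / 22)

    def test_perfect_table(self):
        table = ConfusionTable([[10, 0], [0, 5]], ("absent", "present"),
                               ("absent", "present"))
        bm = binary_metrics(table, "present")
        assert bm.accuracy == bm.sensitivity == bm.specificity == 1.0

    def test_no_real_positives_marks_sensitivity_undefined(self):
        table = ConfusionTable([[10, 0], [2, 0]], ("absent", "present"),
                               ("absent", "present"))
        bm = binary_metrics(table, "present")
        assert np.isnan(bm.sensitivity)
        assert "sensitivity" not in bm.ci


class TestClopperPearson:
    def test_zero_of_four_closed_form(self):
        lo, hi = clopper_pearson(0, 4, 0.95)
        assert lo == 0.0
        assert hi == pytest.approx(1 - 0.025 ** 0.25)

    def test_four_of_four_mirror(self):
        lo, hi = clopper_pearson(4, 4, 0.95)
        assert hi == 1.0
        assert lo == pytest.approx(0.025 ** 0.25)

    def test_zero_of_one_closed_form(self):
        lo, hi = clopper_pearson(0, 1, 0.95)
        assert (lo, hi) == (0.0, pytest.approx(0.975))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            clopper_pearson(1, 0)
        with pytest.raises(ValueError):
            clopper_pearson(5, 4)


def test_qualified_percentage_arithmetic():
    assert qualified_percentage(208, 237) == pytest.approx(100 * 208 / 237)
    assert round(qualified_percentage(208, 237)) == 88


def test_reference_summary_shape():
    df = summarize_reference_tables()
    assert set(df.index) == {"crt_trend", "max_thickness_trend",
                             "srf_presence", "srf_trend", "irc_presence",
                             "irc_trend"}
    assert (df["n"] == 37).all()
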