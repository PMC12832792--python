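"""Contingency construction and the four disproportionality statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pvsignal.contingency import ContingencyTable, build_table, pair_counts
from pvsignal.signals import Thresholds, evaluate_signals
from pvsignal.stats import bcpnn_ic_table, prr, ror
from pvsignal import mgps


class TestBuildTable:
    def test_hand_counted_toy_pairs(self, toy_store):
        # pairs enumerated in the fixture docstring: 7 total
        t = build_table(toy_store, "X", "headache")
        assert (t.a, t.b, t.c, t.d) == (2, 1, 1, 3)
        assert t.n == 7

    def test_absent_drug_gives_zero_drug_cells(self, toy_store):
        t = build_table(toy_store, "no_such_drug", "headache")
        assert t.a == 0 and t.b == 0
        assert t.c == 3  # all headache pairs sit in the background

    def test_unknown_event_raises(self, toy_store):
        with pytest.raises(KeyError, match="no-such-event"):
            build_table(toy_store, "X", "no-such-event")

    def test_soc_level_dedupes_within_report(self, toy_store):
        # r3 reactions nausea+rash -> SOCs gastrointestinal+skin; r4 rash+headache
        counts = pair_counts(toy_store, "Y", level="SOC")
        assert counts.loc["skin", "a"] == 1
        assert counts.loc["gastrointestinal", "a"] == 1

    def test_repeated_pt_counted_once(self):
        from conftest import TOY_VOCAB, make_record
        from pvsignal.records import ReportStore
        store = ReportStore.from_records(
            [make_record("r", reactions=["headache", "headache"])], TOY_VOCAB)
        t = build_table(store, "X", "headache")
        assert t.a == 1

    def test_marginals_consistent_on_synthetic(self, small_universe):
        store, _ = small_universe
        counts = pair_counts(store, "regorafenib")
        n_pairs = len(store.reactions.drop_duplicates())
        assert ((counts["a"] + counts["b"] + counts["c"] + counts["d"]) == n_pairs).all()
        assert (counts["a"] + counts["c"]).equals(
            store.reactions.drop_duplicates()["pt"].value_counts().sort_index().rename(None))


class TestRor:
    def test_perfect_balance_is_null(self):
        res = ror(ContingencyTable(10, 10, 10, 10))
        assert res.estimate == pytest.approx(1.0)
        assert res.ci95[0] < 1.0 < res.ci95[1]

    def test_worked_example_point_and_wald_ci(self):
        # ad/bc = 20*9800/(80*100) = 24.5; CI from the log-scale Wald formula
        res = ror(ContingencyTable(20, 80, 100, 9800))
        assert res.estimate == pytest.approx(24.5)
        se = np.sqrt(1 / 20 + 1 / 80 + 1 / 100 + 1 / 9800)
        assert res.ci95[0] == pytest.approx(24.5 * np.exp(-1.959963984540054 * se))
        assert res.ci95[0] == pytest.approx(14.45, abs=0.05)
        assert res.ci95[1] == pytest.approx(41.55, abs=0.1)
        assert not res.corrected

    def test_zero_cell_triggers_haldane_anscombe(self):
        res = ror(ContingencyTable(0, 10, 10, 100))
        assert res.corrected
        assert res.estimate == pytest.approx(0.5 * 100.5 / (10.5 * 10.5))

    @given(a=st.integers(1, 200), b=st.integers(1, 200),
           c=st.integers(1, 200), d=st.integers(1, 200))
    @settings(max_examples=100, deadline=None)
    def test_transposing_b_and_c_leaves_ror_unchanged(self, a, b, c, d):
        r1 = ror(ContingencyTable(a, b, c, d))
        r2 = ror(ContingencyTable(a, c, b, d))
        assert r1.estimate == pytest.approx(r2.estimate)

    @given(a=st.integers(1, 100), b=st.integers(1, 100),
           c=st.integers(1, 100), d=st.integers(1, 100))
    @settings(max_examples=100, deadline=None)
    def test_null_iff_cross_products_equal(self, a, b, c, d):
        res = ror(ContingencyTable(a, b, c, d))
        if a * d == b * c:
            assert res.estimate == pytest.approx(1.0)
        else:
            assert res.estimate != pytest.approx(1.0)


class TestPrr:
    def test_worked_example(self):
        est, chi2 = prr(ContingencyTable(20, 80, 100, 9800))
        assert est == pytest.approx((20 / 100) / (100 / 9900))  # 19.8
        assert est == pytest.approx(19.8)
        # Yates: n(|ad-bc|-n/2)^2 / [(a+b)(c+d)(a+c)(b+d)]
        assert chi2 == pytest.approx(285.3, abs=0.15)

    def test_null_when_rates_equal(self):
        est, _ = prr(ContingencyTable(10, 90, 20, 180))
        assert est == pytest.approx(1.0)

    def test_zero_a_gives_zero_prr(self):
        est, _ = prr(ContingencyTable(0, 100, 10, 1000))
        assert est == 0.0


class TestBcpnn:
    def test_null_large_counts_ic_near_zero(self):
        t = ContingencyTable(1000, 9000, 10000, 90000)  # a == E
        ic, _ = bcpnn_ic_table(t)
        assert abs(ic) < 0.01

    def test_worked_example(self):
        t = ContingencyTable(20, 80, 100, 9800)
        assert t.expected_a == pytest.approx(1.2)
        ic, ic025 = bcpnn_ic_table(t)
        assert ic == pytest.approx(np.log2(20.5 / 1.7), abs=1e-12)
        assert ic == pytest.approx(3.592, abs=0.001)
        assert ic025 == pytest.approx(3.592 - 3.3 / np.sqrt(20.5) - 2.4 / 20.5**1.5, abs=0.001)
        assert ic025 == pytest.approx(2.838, abs=0.002)

    @given(a=st.integers(0, 500), b=st.integers(0, 500),
           c=st.integers(0, 500), d=st.integers(1, 5000))
    @settings(max_examples=100, deadline=None)
    def test_lower_bound_always_below_ic(self, a, b, c, d):
        ic, ic025 = bcpnn_ic_table(ContingencyTable(a, b, c, d))
        assert ic025 < ic


class TestFlags:
    PRIOR = mgps.MgpsPrior(1.0, 1.0, 2.0, 2.0, 0.5)

    def _frame_for(self, table):
        from conftest import store_for_table
        store = store_for_table(table.a, table.b, table.c, table.d)
        return evaluate_signals(store, "X", prior=self.PRIOR)

    def test_strong_signal_sets_all_four_flags(self):
        frame = self._frame_for(ContingencyTable(20, 80, 100, 9800)).set_index("event")
        row = frame.loc["headache"]
        assert row[["flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps"]].all()
        assert row["positive_all"] and row["positive_any"]

    def test_null_table_sets_no_flags(self):
        frame = self._frame_for(ContingencyTable(10, 10, 10, 10)).set_index("event")
        row = frame.loc["headache"]
        assert not row[["flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps"]].any()

    def test_count_gate_blocks_tiny_a_despite_huge_ror(self):
        frame = self._frame_for(ContingencyTable(2, 1, 1, 996)).set_index("event")
        assert not frame.loc["headache", "flag_ror"]

    @given(a=st.integers(3, 60))
    @settings(max_examples=25, deadline=None)
    def test_increasing_a_never_clears_a_flag(self, a):
        th = Thresholds()
        f1 = self._frame_for(ContingencyTable(a, 50, 40, 2000)).set_index("event").loc["headache"]
        f2 = self._frame_for(ContingencyTable(a + 1, 50, 40, 2000)).set_index("event").loc["headache"]
        for col in ("flag_ror", "flag_prr", "flag_bcpnn", "flag_mgps"):
            assert not (f1[col] and not f2[col])
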