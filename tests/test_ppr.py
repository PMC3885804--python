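from datetime import date

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from pprpanel.ppr import (STRATEGIES, StrategyOptions, adjusted_denominator,
                          build_intervals, compute_patient_ppr,
                          day_coverage_oracle, numerator_days, supply_windows)


def _ics(rows):
    df = pd.DataFrame(rows, columns=["issue_date", "duration_days"])
    df["issue_date"] = pd.to_datetime(df["issue_date"])
    df["dosage_form"] = "inhaler"
    return df


def _o(iso):
    return pd.Timestamp(iso).toordinal()


class TestIntervals:
    def test_three_complete_years_use_365_even_in_leap_years(self):
        iv = build_intervals("2000-01-01", "2003-01-01")
        assert len(iv) == 3
        assert iv["denominator_days"].tolist() == [365, 365, 365]
        assert iv["length_days"].tolist() == [366, 365, 365]  # 2000 is leap

    def test_mid_year_entry_truncates_first_interval(self):
        iv = build_intervals("2000-07-01", "2002-01-01")
        assert iv["denominator_days"].tolist() == [184, 365]
        assert iv["t"].tolist() == [1, 2]

    def test_zero_length_followup_empty(self):
        assert build_intervals("2005-04-01", "2005-04-01").empty


class TestSupplyWindows:
    def test_window_is_halfopen_issue_plus_duration(self):
        s, e, n_unres = supply_windows(_ics([("2001-12-02", 100)]))
        assert (e - s).tolist() == [100]
        assert date.fromordinal(int(e[0])) == date(2002, 3, 12)
        assert n_unres == 0

    def test_duplicate_same_day_windows_both_kept(self):
        s, e, _ = supply_windows(_ics([("2005-02-01", 28), ("2005-02-01", 28)]))
        assert len(s) == 2 and np.array_equal(s, e - 28)

    def test_unresolvable_duration_yields_no_window(self):
        s, _, n_unres = supply_windows(_ics([("2005-02-01", None)]))
        assert len(s) == 0 and n_unres == 1


class TestNumerators:
    def test_overlap_included_vs_excluded(self):
        # two 100-day windows offset by 50 days inside one year
        iv = build_intervals("2005-01-01", "2006-01-01")
        s = np.array([_o("2005-01-01"), _o("2005-02-20")])
        e = s + 100
        num = numerator_days(s, e, iv)
        assert num["multiplicity"][0] == 200
        assert num["union"][0] == 150

    def test_boundary_spanning_window_splits_by_calendar(self):
        iv = build_intervals("2005-01-01", "2007-01-01")
        s = np.array([_o("2005-12-02")])  # 30 days left in 2005
        num = numerator_days(s, s + 100, iv)
        assert num["multiplicity"].tolist() == [30, 70]

    def test_no_windows_all_zero(self):
        iv = build_intervals("2005-01-01", "2007-01-01")
        num = numerator_days(np.empty(0, np.int64), np.empty(0, np.int64), iv)
        assert num["multiplicity"].sum() == 0 and num["union"].sum() == 0

    def test_terminal_excess_and_pre_followup_reported(self):
        iv = build_intervals("2005-01-01", "2006-01-01")
        s = np.array([_o("2004-12-22"), _o("2005-12-22")])
        num = numerator_days(s, s + 20, iv)
        assert num["pre_followup"] == 10
        assert num["terminal_excess"] == 10
        assert num["multiplicity"][0] == 20  # 10 + 10 inside the year

    def test_proportional_sharing_weights_by_denominators(self):
        iv = build_intervals("2005-07-01", "2007-01-01")  # denoms 184, 365
        s = np.array([_o("2005-12-02")])
        num = numerator_days(s, s + 100, iv)
        expect = 100 * np.array([184, 365]) / 549
        np.testing.assert_allclose(num["proportional"], expect)
        assert num["proportional"].sum() == pytest.approx(100)


class TestComputePPR:
    def test_formula_and_censor_rule(self):
        # 500 supply days against denominator 365
        ics = _ics([("2005-01-01", 250), ("2005-01-01", 250)])
        table, dropped = compute_patient_ppr("p", "2005-01-01", "2006-01-01", ics)
        by = table.set_index("strategy")["ppr"]
        assert by[1] == pytest.approx(136.99, abs=0.005)
        assert by[5] == 100.0
        assert not dropped

    def test_known_quotient_69_86(self):
        ics = _ics([("2005-01-01", 255)])
        table, _ = compute_patient_ppr("p", "2005-01-01", "2006-01-01", ics,
                                       strategies=(1,))
        assert table["ppr"].iloc[0] == pytest.approx(69.86, abs=0.005)

    def test_zero_supply_zero_under_all_strategies(self):
        table, _ = compute_patient_ppr("p", "2005-01-01", "2006-01-01",
                                       _ics([]))
        assert (table["ppr"] == 0).all() and len(table) == 5

    def test_strategy_map_matches_table_footnote(self):
        assert STRATEGIES[1] == StrategyOptions("include", "carry_next", "fixed_365", False)
        assert STRATEGIES[2].overlap == "exclude"
        assert STRATEGIES[3].excess == "proportional"
        assert STRATEGIES[4].denominator == "adjusted"
        assert STRATEGIES[5].censor_at_100


class TestAdjustedDenominator:
    def test_single_gap_subtracted(self):
        lo, hi = _o("2005-01-01"), _o("2006-01-01")
        assert adjusted_denominator(lo, hi, [lo + 100], [lo + 130]) == 335

    def test_no_gaps_full_year(self):
        lo, hi = _o("2005-01-01"), _o("2006-01-01")
        assert adjusted_denominator(lo, hi, [], []) == 365

    def test_overlapping_gaps_counted_as_union(self):
        lo, hi = _o("2005-01-01"), _o("2006-01-01")
        gaps_s = [lo + 100, lo + 110]
        gaps_e = [lo + 120, lo + 130]  # union = 30 days
        assert adjusted_denominator(lo, hi, gaps_s, gaps_e) == 335

    def test_gap_covering_whole_interval_drops_patient_year(self):
        ics = _ics([("2005-01-01", None)])
        table, dropped = compute_patient_ppr(
            "p", "2005-01-01", "2006-01-01", ics,
            gap_median_days={"inhaler": 400}, strategies=(4,))
        assert len(table) == 0
        assert dropped[0][3] == "zero denominator"


@st.composite
def _fuzz_case(draw):
    n_windows = draw(st.integers(0, 50))
    start_lo = _o("2004-01-01")
    windows = [(draw(st.integers(start_lo, start_lo + 1200)),
                draw(st.integers(1, 200))) for _ in range(n_windows)]
    entry = draw(st.sampled_from(["2004-01-01", "2004-06-15", "2005-01-01"]))
    exit_ = draw(st.sampled_from(["2006-01-01", "2006-07-02", "2007-01-01"]))
    return windows, entry, exit_


class TestOracleEquivalence:
    def test_whole_year_single_window(self):
        lo, hi = _o("2005-01-01"), _o("2006-01-01")
        assert day_coverage_oracle([lo], [hi], lo, hi) == (365, 365)

    def test_empty_is_zero(self):
        lo, hi = _o("2005-01-01"), _o("2006-01-01")
        assert day_coverage_oracle([], [], lo, hi) == (0, 0)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(_fuzz_case())
    def test_sweep_matches_day_by_day_oracle_and_conserves(self, case):
        windows, entry, exit_ = case
        iv = build_intervals(entry, exit_)
        s = np.array(sorted(w[0] for w in windows), dtype=np.int64)
        durs = {w[0]: [] for w in windows}
        for w0, d in windows:
            durs[w0].append(d)
        s_list, e_list = [], []
        for w0, d in sorted(windows):
            s_list.append(w0)
            e_list.append(w0 + d)
        s = np.array(s_list, dtype=np.int64)
        e = np.array(e_list, dtype=np.int64)
        num = numerator_days(s, e, iv)
        for k, row in iv.iterrows():
            mult, union = day_coverage_oracle(s, e, row["start"], row["end"])
            assert num["multiplicity"][k] == mult
            assert num["union"][k] == union
        # conservation under include-overlap + carry-next
        total = float((e - s).sum())
        assert num["multiplicity"].sum() + num["terminal_excess"] \
            + num["pre_followup"] == pytest.approx(total)

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(_fuzz_case())
    def test_censoring_and_dominance_invariants(self, case):
        windows, entry, exit_ = case
        ics = _ics([(str(date.fromordinal(w0)), d) for w0, d in windows])
        table, _ = compute_patient_ppr("p", entry, exit_, ics)
        wide = table.pivot(index="t", columns="strategy", values="ppr")
        assert (wide[5] <= 100.0 + 1e-9).all()
        assert (wide[2] <= 100.0 + 1e-9).all()
        assert (wide[2] <= wide[1] + 1e-9).all()

    def test_benign_limit_all_strategies_agree(self):
        # non-overlapping windows, none crossing interval boundaries
        ics = _ics([("2005-01-10", 30), ("2005-03-01", 50), ("2005-10-01", 60)])
        table, _ = compute_patient_ppr("p", "2005-01-01", "2006-01-01", ics)
        assert table["ppr"].nunique() == 1
        assert table["ppr"].iloc[0] == pytest.approx(100 * 140 / 365)
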