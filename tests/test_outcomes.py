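"""Outcome summaries, comparisons, currency, and table rendering."""

import numpy as np
import pandas as pd
import pytest

import saltsim as ss
from saltsim.outcomes import percentage_of_base, round_half_up

from conftest import make_uniform_params


class TestCurrencyAndRounding:
    @pytest.mark.parametrize(
        "jpy,rate,usd",
        [(109.01, 109.01, 1.0), (0.0, 109.01, 0.0), (1_090_100.0, 109.01, 10_000.0)],
    )
    def test_conversion(self, jpy, rate, usd):
        assert ss.convert_currency(jpy, rate) == pytest.approx(usd)

    def test_non_positive_rate_rejected(self):
        with pytest.raises(ss.SaltsimError):
            ss.convert_currency(100.0, 0.0)

    @pytest.mark.parametrize(
        "x,decimals,expected",
        [(2.9883, 1, 3.0), (0.25, 1, 0.3), (1.05, 1, 1.1), (2.94, 1, 2.9)],
    )
    def test_half_up_rounding(self, x, decimals, expected):
        assert round_half_up(x, decimals) == expected


class TestSummaries:
    def test_zero_event_trajectory_summarizes_to_zero(self):
        p = make_uniform_params(
            incidence_ihd=0.0, incidence_stroke=0.0,
            mortality_ihd=0.0, mortality_stroke=0.0, all_cause=0.0,
        )
        s = ss.summarize(ss.run_cohort(p, ss.make_scenario(p, "base")), p.costs)
        pooled = s.pooled()
        assert pooled[["incidence_ihd", "incidence_stroke",
                       "deaths_ihd", "deaths_stroke"]].sum() == 0

    def test_one_cycle_sums_equal_the_ledger(self):
        p = make_uniform_params(
            population=1000, prev_ihd=0.1, prev_stroke=0.2,
            incidence_ihd=-np.log(0.99), incidence_stroke=0.0,
            mortality_ihd=0.0, mortality_stroke=0.0, all_cause=0.0,
            first_ever=0.8, case_fatality=0.2,
            outpatient=100.0, inpatient=1000.0, horizon=1,
        )
        s = ss.summarize(ss.run_cohort(p, ss.make_scenario(p, "base")), p.costs)
        row = s.table.loc[("male", "40-49")]
        assert row["incidence_ihd"] == pytest.approx(10.0)
        assert row["deaths_ihd"] == pytest.approx(2.0)
        assert row["outpatient_ihd_jpy"] == pytest.approx(10_000.0)
        assert row["inpatient_ihd_jpy"] == pytest.approx(10_000.0)

    def test_pooled_equals_sum_over_sexes(self, default_params, base_trajectory):
        s = ss.summarize(base_trajectory, default_params.costs)
        by_sex = s.by_sex()
        pd.testing.assert_series_equal(
            by_sex.sum(axis=0), s.pooled(), check_names=False
        )
        pd.testing.assert_series_equal(
            s.table.sum(axis=0), s.pooled(), check_names=False
        )


class TestComparisons:
    def test_identical_summaries_compare_to_zero(self, default_params, base_trajectory):
        s = ss.summarize(base_trajectory, default_params.costs)
        c = ss.compare(s, s)
        assert (c.averted.to_numpy() == 0).all()
        assert c.percent("events") == 0.0 and c.saved_cost_usd() == 0.0

    def test_percentages_recomputable_from_unrounded_counts(
        self, default_params, base_trajectory
    ):
        p = default_params
        s_base = ss.summarize(base_trajectory, p.costs)
        s_8g = ss.summarize(ss.run_cohort(p, ss.make_scenario(p, "8g")), p.costs)
        c = ss.compare(s_base, s_8g)
        bp = s_base.pooled()
        manual = 100.0 * c.averted_events() / float(
            bp["incidence_ihd"] + bp["incidence_stroke"]
        )
        assert c.percent("events") == pytest.approx(manual, rel=1e-12)

    def test_mismatched_strata_rejected(self, default_params, base_trajectory):
        s = ss.summarize(base_trajectory, default_params.costs)
        other = ss.OutcomeSummary(
            scenario="x", table=s.table.iloc[:4],
            population=s.population.iloc[:4], jpy_per_usd=s.jpy_per_usd,
        )
        with pytest.raises(ss.SaltsimError):
            ss.compare(s, other)


class TestRenderedTables:
    def test_projection_table_shape_and_totals(self, default_params, base_trajectory):
        s = ss.summarize(base_trajectory, default_params.costs)
        t = ss.table2(s)
        # one total row + four age rows per sex
        assert len(t) == 10
        men_total = t[(t.sex == "male") & (t.age_group == "40-79")].iloc[0]
        men_ages = t[(t.sex == "male") & (t.age_group != "40-79")]
        assert men_total["population"] == men_ages["population"].sum()
        assert abs(men_total["incidence_ihd"] - men_ages["incidence_ihd"].sum()) <= 2

    def test_comparison_table_is_deterministic(self, default_params, base_trajectory):
        p = default_params
        s_base = ss.summarize(base_trajectory, p.costs)
        comps = [
            ss.compare(
                s_base, ss.summarize(ss.run_cohort(p, ss.make_scenario(p, n)), p.costs)
            )
            for n in ("8g", "6g")
        ]
        a = ss.comparison_table(comps)
        b = ss.comparison_table(comps)
        pd.testing.assert_frame_equal(a, b)
        assert list(a.scenario) == ["8g", "6g"]

    def test_empty_comparison_list_renders_header_only(self):
        t = ss.comparison_table([])
        assert len(t) == 0 and "averted_events_pct" in t.columns

    def test_percentage_of_base_handles_zero_base(self):
        assert percentage_of_base(5.0, 0.0) == 0.0
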