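"""Interval extrapolation, plot averaging, smoothing, Kp reduction, alignment,
and the monitoring bookkeeping table."""

import logging

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import kpgrowth as kg
from kpgrowth import prepare
from kpgrowth.prepare import (
    average_plots,
    daily_kp,
    intervals_to_daily,
    lag_align,
    monitoring_summary,
    moving_average,
    pool_yearly,
    round_half_up,
)

from conftest import make_pattern


def _iv(rows):
    df = pd.DataFrame(rows, columns=["start_date", "end_date", "rate_mm_day"])
    df["start_date"] = pd.to_datetime(df["start_date"])
    df["end_date"] = pd.to_datetime(df["end_date"])
    df["plot_id"] = "P01"
    df["n_shoots"] = 30
    return df


class TestIntervalsToDaily:
    def test_interval_covers_days_after_start(self):
        pat = intervals_to_daily(_iv([("2020-05-01", "2020-05-03", 2.0)]))
        assert list(pat.dates.strftime("%Y-%m-%d")) == ["2020-05-02", "2020-05-03"]
        assert np.allclose(pat.values, 2.0)

    def test_abutting_intervals_step_with_no_gap(self):
        pat = intervals_to_daily(
            _iv([("2020-05-01", "2020-05-03", 1.0), ("2020-05-03", "2020-05-05", 3.0)])
        )
        assert list(pat.values) == [1.0, 1.0, 3.0, 3.0]
        assert (np.diff(pat.dates.to_numpy()).astype("timedelta64[D]") == 1).all()

    def test_empty_input_gives_empty_pattern(self):
        assert len(intervals_to_daily(_iv([]))) == 0

    def test_overlap_rejected_with_collision_named(self):
        with pytest.raises(ValueError, match="overlap"):
            intervals_to_daily(
                _iv([("2020-05-01", "2020-05-04", 1.0), ("2020-05-03", "2020-05-06", 2.0)])
            )

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(1, 5), min_size=1, max_size=12), st.data())
    def test_growth_mass_conserved(self, lengths, data):
        """Daily extrapolation preserves rate x interval-length per interval."""
        start = pd.Timestamp("2021-06-01")
        rows, total = [], 0.0
        for ln in lengths:
            rate = data.draw(st.floats(0, 5, allow_nan=False))
            rows.append((start, start + pd.Timedelta(days=ln), rate))
            total += rate * ln
            start += pd.Timedelta(days=ln)
        pat = intervals_to_daily(_iv(rows))
        assert np.isclose(pat.values.sum(), total)


class TestAveragePlots:
    def test_mean_over_plots(self):
        avg = average_plots([make_pattern([2.0, 2.0]), make_pattern([4.0, 4.0])])
        assert np.allclose(avg.values, 3.0)

    def test_date_missing_from_one_plot_uses_remaining(self):
        a = make_pattern([2.0, 2.0], start="2020-05-01")
        b = make_pattern([4.0], start="2020-05-01")
        avg = average_plots([a, b])
        assert list(avg.values) == [3.0, 2.0]

    def test_single_plot_identity(self):
        a = make_pattern([1.0, 5.0])
        assert np.allclose(average_plots([a]).values, a.values)

    def test_unit_mismatch_rejected(self):
        with pytest.raises(ValueError, match="unit"):
            average_plots([make_pattern([1.0]), make_pattern([1.0], units="degC")])


class TestMovingAverage:
    def test_shrinking_edges_hand_example(self):
        out = moving_average(make_pattern([1, 2, 3, 4, 5]), 3)
        assert np.allclose(out.values, [1.5, 2, 3, 4, 4.5])

    def test_constant_unchanged_and_width_one_identity(self):
        pat = make_pattern([2.0] * 6)
        assert np.allclose(moving_average(pat, 3).values, 2.0)
        wavy = make_pattern([1, 9, 4])
        assert np.allclose(moving_average(wavy, 1).values, wavy.values)

    def test_even_width_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            moving_average(make_pattern([1, 2]), 2)

    def test_never_crosses_the_winter_gap(self):
        y1 = make_pattern([0.0, 0.0, 0.0], start="2020-06-01")
        y2 = make_pattern([9.0, 9.0, 9.0], start="2021-06-01")
        both = kg.DailyPattern(pd.concat([y1.data, y2.data]), "mm/day")
        out = moving_average(both, 3)
        assert np.allclose(out.values, [0, 0, 0, 9, 9, 9])

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=40), st.sampled_from([3, 5, 7]))
    def test_value_range_never_widens(self, values, width):
        pat = make_pattern(values)
        out = moving_average(pat, width)
        assert out.values.min() >= pat.values.min() - 1e-9
        assert out.values.max() <= pat.values.max() + 1e-9


class TestDailyKp:
    def _series(self, day_values):
        idx, vals = [], []
        for day, hourly in day_values.items():
            for h, v in zip(prepare.CANONICAL_HOURS, hourly):
                idx.append(pd.Timestamp(day) + pd.Timedelta(hours=h))
                vals.append(v)
        return pd.Series(vals, index=pd.DatetimeIndex(idx))

    def test_constant_day_same_under_both_aggregators(self):
        s = self._series({"2020-05-01": [2.0] * 8})
        assert daily_kp(s, "mean").values[0] == 2.0
        assert daily_kp(s, "max").values[0] == 2.0

    def test_mean_and_max_aggregation(self):
        s = self._series({"2020-05-01": [0, 0, 0, 0, 1, 1, 1, 1]})
        assert daily_kp(s, "mean").values[0] == 0.5
        assert daily_kp(s, "max").values[0] == 1.0

    def test_incomplete_day_dropped_with_warning(self, caplog):
        s = self._series({"2020-05-01": [1.0] * 8})
        s = pd.concat([s, self._series({"2020-05-02": [2.0] * 8}).iloc[:7]])
        with caplog.at_level(logging.WARNING, logger="kpgrowth.prepare"):
            out = daily_kp(s)
        assert len(out) == 1
        assert "2020-05-02" in caplog.text

    def test_unknown_aggregator_rejected(self):
        with pytest.raises(ValueError, match="aggregator"):
            daily_kp(self._series({"2020-05-01": [1.0] * 8}), "sum")


class TestLagAlign:
    def test_growth_pairs_with_previous_day(self):
        growth = make_pattern([1.0], start="2020-05-02")
        temp = make_pattern([10.0, 99.0], start="2020-05-01", units="degC")
        kp = make_pattern([2.0, 7.0], start="2020-05-01", units="kp")
        rec = lag_align(growth, temp, kp, lag=1)
        assert len(rec) == 1
        assert rec.loc[0, "temperature"] == 10.0 and rec.loc[0, "kp"] == 2.0

    def test_lag_zero_pairs_same_day(self):
        growth = make_pattern([1.0], start="2020-05-02")
        temp = make_pattern([10.0, 99.0], start="2020-05-01", units="degC")
        kp = make_pattern([2.0, 7.0], start="2020-05-01", units="kp")
        rec = lag_align(growth, temp, kp, lag=0)
        assert rec.loc[0, "temperature"] == 99.0 and rec.loc[0, "kp"] == 7.0

    def test_missing_driver_drops_record(self):
        growth = make_pattern([1.0, 1.0], start="2020-05-02")
        temp = make_pattern([10.0], start="2020-05-01", units="degC")  # only day 1
        kp = make_pattern([2.0, 2.0], start="2020-05-01", units="kp")
        rec = lag_align(growth, temp, kp)
        assert len(rec) == 1  # n_growth - n_dropped

    def test_record_count_matches_set_intersection_oracle(self):
        rng = np.random.default_rng(11)
        base = pd.date_range("2020-05-01", periods=60, freq="D")
        for _ in range(20):
            g_days = pd.DatetimeIndex(sorted(rng.choice(base, 30, replace=False)))
            t_days = pd.DatetimeIndex(sorted(rng.choice(base, 40, replace=False)))
            k_days = pd.DatetimeIndex(sorted(rng.choice(base, 40, replace=False)))
            growth = kg.DailyPattern(pd.Series(1.0, index=g_days), "mm/day")
            temp = kg.DailyPattern(pd.Series(0.0, index=t_days), "degC")
            kp = kg.DailyPattern(pd.Series(1.0, index=k_days), "kp")
            rec = lag_align(growth, temp, kp, lag=1)
            shift = pd.Timedelta(days=1)
            expected = {d for d in g_days if d - shift in set(t_days) and d - shift in set(k_days)}
            assert set(rec["date"]) == expected


PRINTED_YEARLY = pd.DataFrame(
    {
        "sampling_events": [34, 68, 88, 89, 77, 102, 92, 90],
        "n_plots": [4, 11, 13, 6, 3, 10, 10, 10],
        "shoots_measured": [9087, 30267, 45278, 31837, 10526, 34195, 24000, 24300],
        "plot_growth_rates": [530, 1365, 1578, 1020, 544, 1706, 1608, 1608],
        "mire_growth_rates": [178, 178, 178, 180, 156, 205, 184, 180],
        "mean_sample_size": [93.7, 59.7, 57.8, 60.0, 46.0, 39.9, 30.0, 30.0],
        "mean_interval_days": [5.2, 2.8, 2.0, 2.1, 2.1, 2.0, 2.0, 2.0],
    },
    index=range(2015, 2023),
)


class TestMonitoringSummary:
    def test_pooled_counts_are_sums_and_means_are_unweighted(self):
        pooled = pool_yearly(PRINTED_YEARLY)
        assert pooled["shoots_measured"] == 209490
        assert pooled["mean_sample_size"] == 52.1
        assert pooled["mean_interval_days"] == 2.5

    def test_single_year_pooled_equals_year(self):
        one = PRINTED_YEARLY.iloc[[2]]
        pooled = pool_yearly(one)
        for col in ("sampling_events", "shoots_measured", "mean_sample_size"):
            assert pooled[col] == one.iloc[0][col]

    def test_zero_event_year_rejected(self):
        tables = {2020: pd.DataFrame(columns=["plot_id", "start_date", "end_date",
                                              "n_shoots", "rate_mm_day"])}
        with pytest.raises(ValueError, match="2020"):
            monitoring_summary(tables)

    def test_counts_match_brute_force_on_random_tables(self):
        rng = np.random.default_rng(7)
        tables = {}
        for year in (2019, 2020, 2021):
            n = int(rng.integers(5, 30))
            start = pd.Timestamp(year, 5, 1) + pd.to_timedelta(
                np.sort(rng.choice(np.arange(0, 120), n, replace=False)), unit="D"
            )
            tables[year] = pd.DataFrame(
                {
                    "plot_id": rng.choice(["A", "B", "C"], n),
                    "start_date": start,
                    "end_date": start + pd.Timedelta(days=2),
                    "n_shoots": rng.integers(20, 60, n),
                    "rate_mm_day": rng.random(n),
                }
            )
        summ = monitoring_summary(tables)
        assert summ.pooled["shoots_measured"] == sum(
            t["n_shoots"].sum() for t in tables.values()
        )
        assert summ.pooled["plot_growth_rates"] == sum(len(t) for t in tables.values())
        assert (summ.yearly.index == [2019, 2020, 2021]).all()

    def test_rounding_is_half_up_not_bankers(self):
        assert round_half_up(0.25, 1) == 0.3
        assert round_half_up(2.525, 1) == 2.5
        assert round_half_up(52.1375, 1) == 52.1
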