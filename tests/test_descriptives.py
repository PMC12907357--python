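"""Frequency tables, onset summaries, yearly series, and the SIDS interval
table."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dtapsafe.cohort import Cohort
from dtapsafe.descriptives import (
    bin_onset_days,
    bin_sids_interval,
    format_percent,
    onset_summary,
    percent,
    sids_interval_table,
    summarize_demographics,
    summarize_vaccines,
    yearly_series,
)
from dtapsafe.vaers_io import Report, VaccineEntry


def _frame(n, **overrides):
    base = {
        "report_id": [str(i) for i in range(n)],
        "received_year": [2000] * n,
        "age_years": [1.0] * n,
        "age_stratum": ["<2"] * n,
        "sex": ["female"] * n,
        "onset_days": [1.0] * n,
        "serious": [False] * n,
        "fatal": [False] * n,
        "primary_outcome": ["Recovered"] * n,
    }
    base.update(overrides)
    return pd.DataFrame(base)


class TestPercent:
    def test_half_up_rounding(self):
        # 0.125% rounds half-up to 0.13, not banker's 0.12
        assert percent(125, 100_000) == 0.13

    def test_zero_count(self):
        assert percent(0, 50) == 0.0

    def test_display_threshold(self):
        # a tiny nonzero share prints as "<0.01%"
        assert format_percent(1, 100_000) == "<0.01%"
        assert format_percent(5246, 10_000) == "52.46%"

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=8))
    @settings(deadline=None, max_examples=50)
    def test_section_percents_sum_to_100(self, counts):
        total = sum(counts)
        if total == 0:
            return
        assert abs(sum(percent(c, total) for c in counts) - 100.0) <= 0.05


class TestDemographics:
    def test_small_fixture_counts(self, small_cohort):
        table = summarize_demographics(small_cohort)
        sex = table[table.section == "gender"].set_index("level")
        assert sex.loc["Female", "count"] == 5
        assert sex.loc["Male", "count"] == 4
        assert sex.loc["N/A", "count"] == 1
        onset = table[table.section == "onset_days"].set_index("level")
        # 1006 (negative onset) and 1011 (missing onset date) have no interval
        assert onset.loc["N/A", "count"] == 2
        assert onset.loc["<30", "count"] == 8

    def test_zero_level_has_zero_percent(self):
        cohort = Cohort.from_frame(_frame(10))
        table = summarize_demographics(cohort)
        row = table[(table.section == "gender") & (table.level == "Male")]
        assert row["count"].iloc[0] == 0 and row["percent"].iloc[0] == 0.0

    def test_sections_sum_to_denominator(self, small_cohort):
        table = summarize_demographics(small_cohort)
        for _, section in table.groupby("section"):
            assert section["count"].sum() == section["denominator"].iloc[0]


class TestOnsetSummary:
    @given(st.lists(st.integers(0, 15000), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=100)
    def test_moments_match_sort_oracle(self, days):
        cohort = Cohort.from_frame(_frame(len(days), onset_days=[float(d) for d in days]))
        summary = onset_summary(cohort)
        ordered = sorted(days)
        assert summary.min == ordered[0]
        assert summary.max == ordered[-1]
        k = len(ordered)
        median = (
            ordered[k // 2] if k % 2 else (ordered[k // 2 - 1] + ordered[k // 2]) / 2
        )
        assert summary.median == pytest.approx(median)
        assert summary.mean == pytest.approx(sum(days) / k)

    @pytest.mark.parametrize(
        "days, expected",
        [(0, "<30"), (29, "<30"), (30, "≥30 and <60"), (359, "≥180 and <360"),
         (360, "≥360"), (14100, "≥360"), (float("nan"), "N/A")],
    )
    def test_bin_edges(self, days, expected):
        assert bin_onset_days(days) == expected

    def test_share_within_one_day(self):
        cohort = Cohort.from_frame(_frame(4, onset_days=[0.0, 1.0, 2.0, np.nan]))
        summary = onset_summary(cohort)
        assert summary.n_within_1_day == 2
        assert summary.share_within_1_day == 50.0


def _vaccine_report(i, brand, dose, manu="M"):
    return Report(
        report_id=str(i), received_date=None, age_years=1.0, sex="female",
        vaccination_date=None, onset_date=None, outcome_flags=frozenset(),
        vaccines=(VaccineEntry(brand, manu, dose),), pts=frozenset({"Pyrexia"}),
    )


class TestVaccines:
    def test_dose_levels_and_denominator(self):
        reports = [
            _vaccine_report(1, "DTAP (INFANRIX)", "1"),
            _vaccine_report(2, "DTAP (INFANRIX)", "7+"),
            _vaccine_report(3, "DTAP (TRIPEDIA)", ""),
            _vaccine_report(4, "FLU (OTHER)", "1"),  # not whitelisted: no dose counted
        ]
        cohort = Cohort.from_frame(_frame(4), reports=reports)
        table = summarize_vaccines(cohort)
        dose = table[table.section == "dose_series"].set_index("level")
        assert dose["denominator"].iloc[0] == 3
        assert dose.loc["7+", "count"] == 1
        assert dose.loc["N/A", "count"] == 1

    def test_single_dose_only_is_100_percent(self):
        reports = [_vaccine_report(i, "DTAP (INFANRIX)", "1") for i in range(5)]
        cohort = Cohort.from_frame(_frame(5), reports=reports)
        table = summarize_vaccines(cohort)
        row = table[(table.section == "dose_series") & (table.level == "1")]
        assert row["percent"].iloc[0] == 100.0


class TestYearlySeries:
    def test_dense_grid_and_conservation(self, small_cohort):
        series = yearly_series(small_cohort)
        years = series["year"].unique()
        assert series.groupby("year").size().nunique() == 1  # dense grid
        assert years.min() == 1999 and years.max() == 2020
        assert series["n_reports"].sum() == len(small_cohort)

    def test_empty_cohort(self):
        cohort = Cohort.from_frame(_frame(0), reports=[])
        assert yearly_series(cohort).empty


def _sids_report(i, onset_days, fatal=True, pt="Sudden infant death syndrome"):
    from datetime import date, timedelta
    vax = date(2020, 1, 1)
    return Report(
        report_id=str(i), received_date=date(2020, 6, 1), age_years=0.3,
        sex="male", vaccination_date=vax,
        onset_date=None if onset_days is None else vax + timedelta(days=onset_days),
        outcome_flags=frozenset({"died"} if fatal else set()),
        vaccines=(VaccineEntry("DTAP (INFANRIX)", "", "1"),),
        pts=frozenset({pt}),
    )


class TestSidsTable:
    def test_hand_computed_bins(self):
        reports = [
            _sids_report(1, 0), _sids_report(2, 3), _sids_report(3, 6),
            _sids_report(4, 29), _sids_report(5, None),
            _sids_report(6, 2, fatal=False),          # not fatal: excluded
            _sids_report(7, 1, pt="Pyrexia"),         # fatal but not SIDS
        ]
        from dtapsafe.cohort import derive_frame
        frame, _ = derive_frame(reports)
        cohort = Cohort(reports=reports, frame=frame)
        table = sids_interval_table(cohort).set_index("bin")
        assert table.loc["0–6", "count"] == 3
        assert table.loc["0–6", "mean_interval_days"] == pytest.approx(3.0)
        assert table.loc["≥29", "count"] == 1
        assert table.loc["NA", "count"] == 1
        assert np.isnan(table.loc["NA", "mean_interval_days"])
        assert table["count"].sum() == 5  # all SIDS cases, nothing else

    @pytest.mark.parametrize(
        "days, expected",
        [(0, "0–6"), (6, "0–6"), (7, "7–13"), (13, "7–13"), (20, "14–20"),
         (28, "21–28"), (29, "≥29"), (float("nan"), "NA")],
    )
    def test_interval_bin_edges(self, days, expected):
        assert bin_sids_interval(days) == expected
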