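"""Cohort construction, daily risk-set bookkeeping, and record parsing."""

from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seasonmort as sm
from seasonmort import cohort_data
from conftest import make_records


@pytest.mark.parametrize(
    "d, expected",
    [
        (date(1862, 2, 13), 43),        # Jan has 31 days, so Feb 13 is day 43
        (date(1862, 1, 1), 0),
        (date(1862, 12, 31), 364),      # non-leap year
        (date(1860, 12, 31), 365),      # leap year
    ],
)
def test_day_of_year(d, expected):
    assert sm.day_of_year(d) == expected


@given(st.integers(min_value=0, max_value=364))
def test_day_of_year_round_trip(offset):
    """day_of_year inverts date arithmetic for every day of a year."""
    d = date(1870, 1, 1) + timedelta(days=offset)
    assert sm.day_of_year(d) == offset


class TestBuildCohort:
    def test_inclusion_rule(self):
        """Members must survive until Jan 1 of the year of the 60th birthday."""
        records = make_records(
            [
                ("1800-06-01", "1860-03-01", "male"),    # died after t0: in
                ("1800-06-01", "1860-01-01", "male"),    # died on t0: in
                ("1800-06-01", "1859-12-31", "male"),    # died before t0: out
                ("1800-06-01", "1870-01-01", "female"),  # wrong sex: out
                ("1801-06-01", "1870-01-01", "male"),    # wrong year: out
            ]
        )
        cohort = sm.build_cohort(records, 1800, "male")
        assert len(cohort) == 2
        assert cohort.t0 == date(1860, 1, 1)
        assert (cohort.members["death_date"] >= pd.Timestamp("1860-01-01")).all()

    def test_empty_cohort_is_valid(self):
        records = make_records([("1800-06-01", "1859-12-31", "male")])
        cohort = sm.build_cohort(records, 1800, "male")
        assert cohort.is_empty

    def test_unknown_sex_rejected(self):
        records = make_records([("1800-06-01", "1860-03-01", "male")])
        with pytest.raises(ValueError, match="sex"):
            sm.build_cohort(records, 1800, "other")


class TestDailyCounts:
    def test_toy_cohort_enumeration(self):
        """Deaths on days 0 and 1 plus one censored member, by hand."""
        records = make_records(
            [
                ("1800-03-15", "1860-01-01", "male"),   # dies day 0
                ("1800-03-15", "1860-01-02", "male"),   # dies day 1
                ("1800-03-15", "1896-06-01", "male"),   # beyond grid: censored
            ]
        )
        counts = sm.build_daily_counts(sm.build_cohort(records, 1800, "male"))
        assert counts.N[0] == 3 and counts.d[0] == 1
        assert counts.N[1] == 2 and counts.d[1] == 1
        assert np.all(counts.N[2:] == 1) and np.all(counts.d[2:] == 0)
        assert counts.n_censored == 1
        # grid runs from 1860-01-01 to 1895-12-31 over actual calendar days
        assert counts.n_days == (date(1896, 1, 1) - date(1860, 1, 1)).days

    def test_pure_censoring(self):
        records = make_records([("1800-03-15", "1896-06-01", "male")] * 2)
        counts = sm.build_daily_counts(sm.build_cohort(records, 1800, "male"))
        assert counts.d.sum() == 0
        assert np.all(counts.N == 2)

    def test_risk_set_bookkeeping_and_conservation(self, small_study):
        """N_t = N_0 - cumulative deaths; censored + died = N_0."""
        _, records = small_study
        for year in (1820, 1880):
            cohort = sm.build_cohort(records, year, "female")
            counts = sm.build_daily_counts(cohort)
            expected_N = counts.N[0] - np.concatenate([[0], np.cumsum(counts.d)[:-1]])
            np.testing.assert_array_equal(counts.N, expected_N)
            assert counts.d.sum() + counts.n_censored == len(cohort)
            assert np.all(counts.d <= counts.N)

    def test_empty_cohort_rejected(self):
        cohort = sm.Cohort(1800, "male", make_records([]).iloc[:0])
        with pytest.raises(ValueError, match="empty"):
            sm.build_daily_counts(cohort)


class TestObservedMeanLifespan:
    def test_two_member_mean(self):
        base = date(1800, 1, 1)
        records = make_records(
            [
                (str(base), str(base + timedelta(days=round(70 * 365.25))), "male"),
                (str(base), str(base + timedelta(days=round(80 * 365.25))), "male"),
            ]
        )
        cohort = sm.build_cohort(records, 1800, "male")
        assert sm.observed_mean_lifespan(cohort) == pytest.approx(75.0, abs=0.01)

    def test_empty_cohort_errors(self):
        cohort = sm.Cohort(1800, "male", make_records([]).iloc[:0])
        with pytest.raises(ValueError):
            sm.observed_mean_lifespan(cohort)


class TestReadPersons:
    def test_csv_and_tsv_with_date_dialects(self, tmp_path):
        csv = tmp_path / "people.csv"
        csv.write_text(
            "birth_date,death_date,sex\n"
            "1800-02-13,1875-03-01,M\n"
            "18010401,18820115,kvinna\n"
        )
        df = cohort_data.read_persons(csv)
        assert list(df["sex"]) == ["male", "female"]
        assert df.loc[1, "birth_date"] == pd.Timestamp("1801-04-01")

        tsv = tmp_path / "people.tsv"
        tsv.write_text("birth_date\tdeath_date\tsex\n1800-02-13\t1875-03-01\t2\n")
        df = cohort_data.read_persons(tsv)
        assert list(df["sex"]) == ["female"]

    def test_bad_dates_dropped_and_bad_sex_raises(self, tmp_path):
        path = tmp_path / "people.csv"
        path.write_text(
            "birth_date,death_date,sex\n"
            "1800-02-13,1875-03-01,M\n"
            "1800-XX-13,1875-03-01,M\n"      # unparseable birth date
            "1800-02-13,1799-01-01,M\n"      # death before birth
        )
        df = cohort_data.read_persons(path)
        assert len(df) == 1

        path.write_text("birth_date,death_date,sex\n1800-02-13,1875-03-01,X\n")
        with pytest.raises(ValueError, match="sex codes"):
            cohort_data.read_persons(path)

    def test_custom_columns(self, tmp_path):
        path = tmp_path / "people.csv"
        path.write_text("fodd,dod,kon\n1800-02-13,1875-03-01,1\n")
        df = cohort_data.read_persons(path, birth_col="fodd", death_col="dod", sex_col="kon")
        assert list(df["sex"]) == ["male"]


def test_person_record_invariants():
    with pytest.raises(ValueError):
        sm.PersonRecord(date(1800, 1, 1), date(1799, 1, 1), "male")
    rec = sm.PersonRecord(date(1800, 1, 1), date(1875, 1, 1), "female")
    assert rec.lifespan_days == (date(1875, 1, 1) - date(1800, 1, 1)).days
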