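"""Person-level records, cohort construction, and daily risk-set/death series.

A birth cohort is the set of people of one sex born in one calendar year who
survived until January 1 of the year of their 60th birthday.  Follow-up time
for a cohort is measured in whole days from that January 1 (``t0``), so that
seasonal structure lines up across individuals; a member's age on day ``t`` is
``365 - b + t`` days past their 59th birthday, where ``b`` is the birth
day-of-year.

The central derived object is :class:`DailyCounts`: for each day ``t`` of the
follow-up grid, the number of persons alive at the start of the day (``N``)
and the number who died during it (``d``).  Deaths after the grid end (the
year of the 95th birthday by default) are right-censored: the person keeps
contributing exposure but no death event.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Accepted spellings for the sex column, case-insensitive.
DEFAULT_SEX_MAP = {
    "m": "male",
    "male": "male",
    "man": "male",
    "1": "male",
    "f": "female",
    "female": "female",
    "kvinna": "female",
    "woman": "female",
    "2": "female",
}

SEXES = ("male", "female")


@dataclass(frozen=True)
class PersonRecord:
    """One individual: birth date, death date, sex ('male' or 'female')."""

    birth_date: date
    death_date: date
    sex: str

    def __post_init__(self) -> None:
        if self.death_date <= self.birth_date:
            raise ValueError(
                f"death_date {self.death_date} not after birth_date {self.birth_date}"
            )
        if self.sex not in SEXES:
            raise ValueError(f"unknown sex {self.sex!r}; expected one of {SEXES}")

    @property
    def lifespan_days(self) -> int:
        return (self.death_date - self.birth_date).days


@dataclass
class Cohort:
    """All members of one sex born in one year who survived until ``t0``.

    ``t0`` is January 1 of ``birth_year + 60``, the origin of the follow-up
    clock.  ``members`` is a DataFrame with datetime64 columns ``birth_date``
    and ``death_date`` (one row per person).
    """

    birth_year: int
    sex: str
    members: pd.DataFrame
    t0: date = field(init=False)

    def __post_init__(self) -> None:
        self.t0 = date(self.birth_year + 60, 1, 1)

    def __len__(self) -> int:
        return len(self.members)

    @property
    def is_empty(self) -> bool:
        return len(self.members) == 0

    @property
    def label(self) -> str:
        return f"{self.birth_year}-{self.sex}"

    def birth_days(self) -> np.ndarray:
        """Day-of-year of birth, ``b``, for each member (Jan 1 -> 0)."""
        bd = self.members["birth_date"].dt
        return (bd.dayofyear - 1).to_numpy()


@dataclass
class DailyCounts:
    """Daily risk-set sizes and death counts on the follow-up grid.

    ``t_grid`` indexes actual calendar days from ``t0`` (day 0) to the last
    day of the grid, so leap years make some cohort grids a day longer.
    ``N[t]`` is the number alive at the beginning of day ``t``; ``d[t]`` the
    number who died during day ``t`` (these people are counted in ``N[t]``).
    """

    cohort_label: str
    birth_year: int
    sex: str
    t0: date
    t_grid: np.ndarray
    N: np.ndarray
    d: np.ndarray
    b_mean: float
    n_censored: int

    def __post_init__(self) -> None:
        if np.any(self.d < 0) or np.any(self.N < 0):
            raise ValueError("negative counts")
        if np.any(self.d > self.N):
            raise ValueError("more deaths than persons at risk on some day")

    @property
    def n_days(self) -> int:
        return len(self.t_grid)

    def dates(self) -> pd.DatetimeIndex:
        return pd.Timestamp(self.t0) + pd.to_timedelta(self.t_grid, unit="D")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "cohort": self.cohort_label,
                "sex": self.sex,
                "t": self.t_grid,
                "date": self.dates(),
                "N": self.N,
                "d": self.d,
            }
        )


def day_of_year(d: date) -> int:
    """Days elapsed since January 1 of the year of ``d`` (January 1 -> 0)."""
    return d.timetuple().tm_yday - 1


def read_persons(
    path,
    birth_col: str = "birth_date",
    death_col: str = "death_date",
    sex_col: str = "sex",
    sex_map: dict[str, str] | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a delimited person-level file into the canonical schema.

    The delimiter is sniffed when ``sep`` is None (handles CSV and TSV).
    Dates may be ISO-8601 (``YYYY-MM-DD``) or compact ``YYYYMMDD``.  Rows with
    unparseable dates or unknown sex codes are dropped with a logged count;
    genealogical sources often contain incomplete dates and no imputation is
    attempted.
    """
    sex_map = {k.lower(): v for k, v in (sex_map or DEFAULT_SEX_MAP).items()}
    df = pd.read_csv(path, sep=sep, engine="python", dtype=str)
    missing = [c for c in (birth_col, death_col, sex_col) if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {path}; found {list(df.columns)}")
    n_raw = len(df)

    def parse_dates(s: pd.Series) -> pd.Series:
        out = pd.to_datetime(s, format="%Y-%m-%d", errors="coerce")
        compact = out.isna()
        if compact.any():
            out[compact] = pd.to_datetime(s[compact], format="%Y%m%d", errors="coerce")
        return out

    out = pd.DataFrame(
        {
            "birth_date": parse_dates(df[birth_col]),
            "death_date": parse_dates(df[death_col]),
            "sex": df[sex_col].str.strip().str.lower().map(sex_map),
        }
    )
    bad_sex = out["sex"].isna() & df[sex_col].notna()
    if bad_sex.any():
        codes = sorted(df.loc[bad_sex, sex_col].unique())
        raise ValueError(f"unknown sex codes {codes}; extend sex_map to read this file")
    ok = out["birth_date"].notna() & out["death_date"].notna()
    ok &= out["death_date"] > out["birth_date"]
    n_dropped = n_raw - int(ok.sum())
    if n_dropped:
        logger.info("dropped %d of %d rows with unparseable or inconsistent dates", n_dropped, n_raw)
    return out[ok].reset_index(drop=True)


def build_cohort(records: pd.DataFrame, birth_year: int, sex: str) -> Cohort:
    """Select the members of a sex-specific birth cohort.

    Inclusion requires death on or after January 1 of ``birth_year + 60``
    (survival until the beginning of the year of the 60th birthday).  An empty
    result is a valid (flagged) cohort.
    """
    if sex not in SEXES:
        raise ValueError(f"unknown sex {sex!r}; expected one of {SEXES}")
    t0 = pd.Timestamp(date(birth_year + 60, 1, 1))
    sel = (
        (records["sex"] == sex)
        & (records["birth_date"].dt.year == birth_year)
        & (records["death_date"] >= t0)
    )
    members = records[sel].reset_index(drop=True)
    if members.empty:
        logger.warning("empty cohort: birth_year=%d sex=%s", birth_year, sex)
    return Cohort(birth_year=birth_year, sex=sex, members=members)


def build_daily_counts(cohort: Cohort, end_age_year: int = 95) -> DailyCounts:
    """Tabulate the daily risk set and death counts for a cohort.

    Day 0 is ``t0``; the grid ends on December 31 of
    ``birth_year + end_age_year``.  Deaths dated after the grid end are
    right-censored: those members appear in ``N`` on every day but contribute
    no death count.
    """
    if cohort.is_empty:
        raise ValueError(f"cannot build daily counts for empty cohort {cohort.label}")
    t0 = pd.Timestamp(cohort.t0)
    grid_end = pd.Timestamp(date(cohort.birth_year + end_age_year, 12, 31))
    n_days = (grid_end - t0).days + 1

    death_t = (cohort.members["death_date"] - t0).dt.days.to_numpy()
    if np.any(death_t < 0):
        raise ValueError("member died before t0; cohort violates the inclusion rule")
    in_grid = death_t < n_days
    n_censored = int((~in_grid).sum())

    d = np.bincount(death_t[in_grid], minlength=n_days).astype(np.int64)
    N0 = len(cohort)
    # alive at the beginning of day t: N0 minus deaths strictly before t
    N = N0 - np.concatenate([[0], np.cumsum(d)[:-1]])
    return DailyCounts(
        cohort_label=cohort.label,
        birth_year=cohort.birth_year,
        sex=cohort.sex,
        t0=cohort.t0,
        t_grid=np.arange(n_days),
        N=N,
        d=d,
        b_mean=float(np.mean(cohort.birth_days())),
        n_censored=n_censored,
    )


def observed_mean_lifespan(cohort: Cohort) -> float:
    """Mean age at death (years) over the members of an extinct cohort.

    Exact day counts divided by 365.25.
    """
    if cohort.is_empty:
        raise ValueError(f"mean lifespan undefined for empty cohort {cohort.label}")
    days = (cohort.members["death_date"] - cohort.members["birth_date"]).dt.days
    return float(days.mean() / 365.25)
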