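"""Population mortality rate tables.

A :class:`RateTable` holds the daily population (background) hazard on a
complete sex x integer-age x calendar-year grid, as read from national life
tables or generated synthetically.  For an individual with known sex, age at
entry and entry date, the table induces a piecewise-constant daily hazard path
over follow-up: the hazard value changes on each January 1st (calendar-year
step) and on each birthday (attained-age step).  Population survival is the
exponentiated negative cumulative sum of that path in one-day steps.

Units: hazards are per day throughout; ages in the grid are completed years;
dates are integer days since 1960-01-01; one year of age is 365.241 days.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._calendar import DAYS_PER_YEAR, year_of_day

MALE, FEMALE = 1, 2
_SEXES = (MALE, FEMALE)


class RateTableError(ValueError):
    """Malformed or incomplete rate-table input."""


@dataclass
class Demographics:
    """Per-individual demographic data used for rate-table lookup.

    Parameters
    ----------
    age_at_entry : int
        Age at entry in days.
    sex : int
        1 = male, 2 = female.
    entry_date : int
        Entry (diagnosis) date as days since 1960-01-01.
    """

    age_at_entry: int
    sex: int
    entry_date: int

    def __post_init__(self):
        if self.age_at_entry < 0:
            raise ValueError("age_at_entry must be >= 0 days")
        if self.sex not in _SEXES:
            raise ValueError(f"sex must be 1 (male) or 2 (female), got {self.sex}")


@dataclass
class RateTable:
    """Daily population hazard on a complete (sex, age, year) grid.

    ``hazard[s, a, y]`` is the per-day hazard for sex ``sexes[s]``, completed
    age ``ages[a]`` and calendar year ``years[y]``.
    """

    ages: np.ndarray          # contiguous integer ages 0..A_max
    years: np.ndarray         # contiguous calendar years
    hazard: np.ndarray        # shape (2, n_ages, n_years), per day
    sexes: tuple = _SEXES
    _warned_clamp: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=int)
        self.years = np.asarray(self.years, dtype=int)
        self.hazard = np.asarray(self.hazard, dtype=float)
        if self.hazard.shape != (len(self.sexes), len(self.ages), len(self.years)):
            raise RateTableError(
                f"hazard shape {self.hazard.shape} does not match grid "
                f"({len(self.sexes)}, {len(self.ages)}, {len(self.years)})"
            )
        if not (np.diff(self.ages) == 1).all():
            raise RateTableError("ages must be contiguous integers")
        if not (np.diff(self.years) == 1).all():
            raise RateTableError("years must be contiguous integers")
        if not np.isfinite(self.hazard).all() or (self.hazard < 0).any():
            raise RateTableError("hazards must be finite and >= 0")

    @property
    def age_max(self) -> int:
        return int(self.ages[-1])

    def to_frame(self) -> pd.DataFrame:
        """Long-format frame with columns sex, age, year, value (daily hazard)."""
        sex, age, year = np.meshgrid(
            self.sexes, self.ages, self.years, indexing="ij"
        )
        return pd.DataFrame(
            {
                "sex": sex.ravel(),
                "age": age.ravel(),
                "year": year.ravel(),
                "value": self.hazard.ravel(),
            }
        )

    def write(self, path) -> None:
        """Write as delimited text (daily-hazard dialect); lossless floats."""
        self.to_frame().to_csv(path, index=False, float_format="%.17g")

    # -- lookups ---------------------------------------------------------

    def _indices(self, sex, age_years, year):
        """Grid indices for (sex, completed age, calendar year) arrays.

        Ages above the last table row clamp to it (with a one-time warning);
        calendar years outside the table raise (no extrapolation).
        """
        sex = np.asarray(sex, dtype=int)
        age_years = np.asarray(age_years, dtype=int)
        year = np.asarray(year, dtype=int)
        if (year < self.years[0]).any() or (year > self.years[-1]).any():
            bad = np.unique(year[(year < self.years[0]) | (year > self.years[-1])])
            raise RateTableError(
                f"calendar year(s) {bad.tolist()} outside table range "
                f"{self.years[0]}..{self.years[-1]}"
            )
        if (age_years > self.age_max).any() and not self._warned_clamp:
            warnings.warn(
                f"ages above {self.age_max} clamped to the last table row",
                stacklevel=3,
            )
            self._warned_clamp = True
        ai = np.clip(age_years, 0, self.age_max) - self.ages[0]
        if (ai < 0).any():
            raise RateTableError("age below table range")
        return sex - 1, ai, year - self.years[0]

    def lookup(self, sex, age_years, year):
        """Daily hazard at (sex, completed age, calendar year)."""
        si, ai, yi = self._indices(sex, age_years, year)
        return self.hazard[si, ai, yi]


# ---------------------------------------------------------------------------
# construction / IO


def load_ratetable(path, dialect: str = "daily_hazard") -> RateTable:
    """Read a rate table from delimited text.

    The file must have columns ``sex,age,year,value`` covering a complete
    (sex, age, year) grid.  ``dialect`` selects the unit of ``value``:

    - ``daily_hazard`` -- value is the per-day hazard, used as is;
    - ``annual_prob`` -- value is the annual death probability q, converted to
      a per-day hazard by ``lambda_d = -log(1 - q) / 365.241``.
    """
    if dialect not in ("daily_hazard", "annual_prob"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = {"sex", "age", "year", "value"} - set(df.columns)
    if missing:
        raise RateTableError(f"rate-table file missing columns {sorted(missing)}")
    return ratetable_from_frame(df, dialect=dialect)


def ratetable_from_frame(df: pd.DataFrame, dialect: str = "daily_hazard") -> RateTable:
    """Build a :class:`RateTable` from a long-format frame (see load_ratetable)."""
    ages = np.arange(df["age"].min(), df["age"].max() + 1)
    years = np.arange(df["year"].min(), df["year"].max() + 1)
    value = df["value"].to_numpy(dtype=float)
    if dialect == "annual_prob":
        if (value >= 1).any():
            bad = df.loc[value >= 1].iloc[0]
            raise RateTableError(
                f"annual probability >= 1 at (sex={int(bad.sex)}, "
                f"age={int(bad.age)}, year={int(bad.year)})"
            )
        value = -np.log1p(-value) / DAYS_PER_YEAR

    hazard = np.full((2, len(ages), len(years)), np.nan)
    si = df["sex"].to_numpy(dtype=int) - 1
    if ((si < 0) | (si > 1)).any():
        raise RateTableError("sex must be coded 1 (male) or 2 (female)")
    ai = df["age"].to_numpy(dtype=int) - ages[0]
    yi = df["year"].to_numpy(dtype=int) - years[0]
    hazard[si, ai, yi] = value
    if np.isnan(hazard).any():
        s, a, y = np.argwhere(np.isnan(hazard))[0]
        raise RateTableError(
            f"incomplete grid: missing cell (sex={s + 1}, age={ages[a]}, "
            f"year={years[y]})"
        )
    return RateTable(ages=ages, years=years, hazard=hazard)


def make_synthetic_ratetable(
    makeham_a: float = 7e-7,
    gompertz_b: float = 1.9e-7,
    gompertz_c: float = 0.092,
    sex_ratio: float = 0.55,
    annual_improvement: float = 0.99,
    years=(1985, 2015),
    age_max: int = 110,
) -> RateTable:
    """Synthetic Makeham-Gompertz population table.

    Male daily hazard at completed age ``a`` in calendar year ``y``::

        (makeham_a + gompertz_b * exp(gompertz_c * a)) * annual_improvement**(y - y0)

    Female cells are the male cells times ``sex_ratio``.  Defaults give a
    1990s-style mortality level: a cohort aged 45-75 followed for ten years
    accumulates a population-death probability of roughly 0.23.

    Parameters are per day (``makeham_a``, ``gompertz_b``), per year of age
    (``gompertz_c``), and dimensionless multipliers (``sex_ratio``,
    ``annual_improvement`` in (0, 1]).
    """
    if makeham_a < 0 or gompertz_b < 0 or gompertz_c <= 0 or sex_ratio <= 0:
        raise ValueError("makeham/gompertz parameters must be positive")
    if not (0 < annual_improvement <= 1):
        raise ValueError("annual_improvement must be in (0, 1]")
    ages = np.arange(0, age_max + 1)
    yrs = np.arange(years[0], years[1] + 1)
    base = makeham_a + gompertz_b * np.exp(gompertz_c * ages)        # (n_ages,)
    trend = annual_improvement ** (yrs - yrs[0])                     # (n_years,)
    male = base[:, None] * trend[None, :]
    hazard = np.stack([male, sex_ratio * male])
    return RateTable(ages=ages, years=yrs, hazard=hazard)


# ---------------------------------------------------------------------------
# hazard paths and population survival


def hazard_path(rt: RateTable, d: Demographics, horizon: int) -> np.ndarray:
    """Daily population hazard over follow-up for one individual.

    Entry ``u`` (1-based day ``u``, array index ``u - 1``) is the table hazard
    at completed age ``floor((age_at_entry + u) / 365.241)`` and the calendar
    year containing day ``entry_date + u``; the path is piecewise constant
    with breakpoints exactly at January 1sts and (365.241-day-convention)
    birthdays.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1 day")
    u = np.arange(1, horizon + 1)
    return rt.lookup(
        np.full(horizon, d.sex),
        ((d.age_at_entry + u) / DAYS_PER_YEAR).astype(int),
        year_of_day(d.entry_date + u),
    )


def hazard_path_matrix(
    rt: RateTable,
    age_at_entry: np.ndarray,
    sex: np.ndarray,
    entry_date: np.ndarray,
    horizon: int,
) -> np.ndarray:
    """Vectorised :func:`hazard_path` for a whole cohort.

    Returns an ``(n, horizon)`` array whose row ``i`` is the daily hazard
    path of individual ``i``.  This is the workhorse behind the weighted
    processes and the simulator; it materialises the full daily grid once so
    downstream cumulative sums are plain vector operations.
    """
    if horizon < 1:
        raise ValueError("horizon must be >= 1 day")
    age_at_entry = np.asarray(age_at_entry, dtype="int64")
    sex = np.asarray(sex, dtype="int32")
    entry_date = np.asarray(entry_date, dtype="int64")
    u = np.arange(1, horizon + 1, dtype="int32")
    # range checks on the extremes only; the grid walk below stays in int32
    y_lo = year_of_day(int(entry_date.min()) + 1)
    y_hi = year_of_day(int(entry_date.max()) + horizon)
    if y_lo < rt.years[0] or y_hi > rt.years[-1]:
        raise RateTableError(
            f"follow-up spans calendar years {y_lo}..{y_hi}, outside table "
            f"range {rt.years[0]}..{rt.years[-1]}"
        )
    max_age = (int(age_at_entry.max()) + horizon) / DAYS_PER_YEAR
    if max_age > rt.age_max and not rt._warned_clamp:
        warnings.warn(
            f"ages above {rt.age_max} clamped to the last table row",
            stacklevel=2,
        )
        rt._warned_clamp = True
    ai = (
        (age_at_entry[:, None] + u[None, :]) / DAYS_PER_YEAR
    ).astype("int32")
    np.clip(ai, 0, rt.age_max, out=ai)
    # years change on true-calendar Jan 1sts: map day numbers through a
    # per-day year lookup covering the span actually needed
    days = (entry_date[:, None] + u[None, :]).astype("int32")
    d0 = int(days.min())
    yi_lut = (
        year_of_day(np.arange(d0, int(days.max()) + 1)) - rt.years[0]
    ).astype("int32")
    n_ages, n_years = len(rt.ages), len(rt.years)
    flat = (ai - np.int32(rt.ages[0])) * np.int32(n_years)
    flat += (sex[:, None] - 1) * np.int32(n_ages * n_years)
    flat += yi_lut[days - np.int32(d0)]
    return rt.hazard.ravel()[flat]


def pop_survival(rt: RateTable, d: Demographics, t: int) -> float:
    """Population survival S_P(t) = exp(-sum of the daily hazard path to t).

    ``t`` in days; ``S_P(0) = 1``.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0:
        return 1.0
    return float(np.exp(-hazard_path(rt, d, t).sum()))
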