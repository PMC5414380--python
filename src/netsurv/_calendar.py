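"""Calendar helpers.

Dates are integer days since 1960-01-01 (day 0 = 1960-01-01).  Calendar-year
boundaries (January 1st) follow the true Gregorian calendar; age arithmetic
elsewhere uses the 365.241-day-year convention instead.
"""

from __future__ import annotations

import numpy as np

EPOCH = np.datetime64("1960-01-01", "D")

#: days per year used for age arithmetic
DAYS_PER_YEAR = 365.241


def year_of_day(day):
    """Calendar year containing ``day`` (integer days since 1960-01-01).

    Accepts scalars or arrays; vectorised via numpy datetime arithmetic.
    """
    d = np.asarray(day, dtype="int64")
    years = (EPOCH + d).astype("datetime64[Y]").astype(int) + 1970
    if np.isscalar(day) or years.ndim == 0:
        return int(years)
    return years


def day_of_date(year: int, month: int = 1, day: int = 1) -> int:
    """Integer day number (since 1960-01-01) of a calendar date."""
    d = np.datetime64(f"{year:04d}-{month:02d}-{day:02d}", "D")
    return int((d - EPOCH).astype(int))
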