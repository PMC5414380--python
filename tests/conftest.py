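import numpy as np
import pytest

from netsurv import Cohort, RateTable, make_synthetic_ratetable


def make_flat_ratetable(daily_hazard, ages=(0, 110), years=(1985, 2015)):
    """Rate table with the same hazard in every cell."""
    a = np.arange(ages[0], ages[1] + 1)
    y = np.arange(years[0], years[1] + 1)
    return RateTable(
        ages=a, years=y, hazard=np.full((2, len(a), len(y)), float(daily_hazard))
    )


@pytest.fixture(scope="session")
def zero_rt():
    """Zero population hazard: weights collapse to 1, S_P = 1."""
    return make_flat_ratetable(0.0)


@pytest.fixture(scope="session")
def const_rt():
    """Constant population hazard of 1e-4 per day in every cell."""
    return make_flat_ratetable(1e-4)


@pytest.fixture(scope="session")
def synth_rt():
    return make_synthetic_ratetable()


def random_cohort(rng, n, k=2, tau=1500, tied=True, strata=None):
    """Small random cohort with demographics resolvable in the fixtures."""
    if tied:
        time = rng.integers(1, tau, size=n)
    else:
        time = rng.choice(np.arange(1, 4 * n + 1), size=n, replace=False)
    return Cohort(
        time=time,
        status=rng.integers(0, 2, size=n),
        age_at_entry=rng.integers(40 * 365, 75 * 365, size=n),
        sex=rng.integers(1, 3, size=n),
        entry_date=rng.integers(11000, 14200, size=n),
        group=rng.integers(0, k, size=n),
        stratum=None if strata is None else rng.integers(0, strata, size=n),
    )
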