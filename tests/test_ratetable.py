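import io

import numpy as np
import pytest

from netsurv import (
    Demographics,
    hazard_path,
    load_ratetable,
    make_synthetic_ratetable,
    pop_survival,
)
from netsurv.ratetable import (
    DAYS_PER_YEAR,
    RateTable,
    RateTableError,
    ratetable_from_frame,
)

from ._oracles import calendar_walk_hazard
from .conftest import make_flat_ratetable


def _csv(text):
    return io.StringIO(text)


class TestLoading:
    @pytest.mark.parametrize(
        "q, expected",
        [(0.0, 0.0), (1 - np.exp(-DAYS_PER_YEAR * 1e-4), 1e-4)],
    )
    def test_annual_probability_conversion(self, q, expected):
        rows = ["sex,age,year,value"]
        for s in (1, 2):
            rows.append(f"{s},50,1995,{float(q)!r}")
        rt = load_ratetable(_csv("\n".join(rows)), dialect="annual_prob")
        assert rt.hazard == pytest.approx(expected, abs=1e-18)

    def test_probability_of_one_rejected(self):
        txt = "sex,age,year,value\n1,50,1995,1.0\n2,50,1995,0.5\n"
        with pytest.raises(RateTableError, match="probability >= 1"):
            load_ratetable(_csv(txt), dialect="annual_prob")

    def test_missing_cell_named(self):
        txt = (
            "sex,age,year,value\n"
            "1,50,1995,0.001\n1,51,1995,0.001\n2,51,1995,0.001\n"
        )
        with pytest.raises(RateTableError, match=r"sex=2, age=50, year=1995"):
            load_ratetable(_csv(txt))

    def test_roundtrip_exact(self, synth_rt):
        buf = io.StringIO()
        synth_rt.write(buf)
        buf.seek(0)
        rt2 = load_ratetable(buf)
        assert np.array_equal(rt2.hazard, synth_rt.hazard)
        assert np.array_equal(rt2.ages, synth_rt.ages)
        assert np.array_equal(rt2.years, synth_rt.years)

    def test_bad_grid_rejected(self):
        with pytest.raises(RateTableError):
            RateTable(
                ages=np.array([50, 52]),
                years=np.array([1995]),
                hazard=np.zeros((2, 2, 1)),
            )


class TestSynthetic:
    def test_gompertz_zero_gives_constant_hazard(self):
        rt = make_synthetic_ratetable(makeham_a=1e-5, gompertz_b=0.0)
        assert np.allclose(rt.hazard[0, :, 0], 1e-5)

    def test_no_improvement_gives_identical_years(self):
        rt = make_synthetic_ratetable(annual_improvement=1.0)
        assert np.all(rt.hazard == rt.hazard[:, :, :1])

    def test_sex_ratio_applies_to_female_cells(self):
        rt = make_synthetic_ratetable(sex_ratio=0.5)
        assert np.allclose(rt.hazard[1], 0.5 * rt.hazard[0])

    def test_covers_very_old_ages(self):
        assert make_synthetic_ratetable().age_max >= 110

    @pytest.mark.parametrize(
        "kw", [{"gompertz_c": -1.0}, {"annual_improvement": 1.5}, {"sex_ratio": 0}]
    )
    def test_invalid_parameters_rejected(self, kw):
        with pytest.raises(ValueError):
            make_synthetic_ratetable(**kw)


class TestHazardPath:
    def test_constant_table_gives_constant_path(self, const_rt):
        d = Demographics(age_at_entry=20000, sex=1, entry_date=12000)
        assert np.all(hazard_path(const_rt, d, 500) == 1e-4)

    def test_birthday_breakpoint_matches_calendar_walk(self):
        # entry exactly on the 60th birthday; ages 60/61 differ, one year
        ages = np.arange(0, 111)
        years = np.arange(1985, 2015)
        h1, h2 = 1e-4, 3e-4
        hz = np.full((2, len(ages), len(years)), h1)
        hz[:, 61:, :] = h2
        rt = RateTable(ages=ages, years=years, hazard=hz)
        age_days = int(np.floor(60 * DAYS_PER_YEAR))
        d = Demographics(age_at_entry=age_days, sex=1, entry_date=12000)
        path = hazard_path(rt, d, 400)
        oracle = calendar_walk_hazard(rt, age_days, 1, 12000, 400)
        assert np.array_equal(path, oracle)
        # first ~365 days at the age-60 value, remainder at the age-61 value
        switch = int(np.argmax(path == h2))
        assert 364 <= switch <= 366
        assert np.all(path[:switch] == h1) and np.all(path[switch:] == h2)

    def test_january_first_breakpoint(self, synth_rt):
        # entry Dec 1, 1995: the year column changes at Jan 1, 1996
        from netsurv._calendar import day_of_date

        entry = day_of_date(1995, 12, 1)
        d = Demographics(age_at_entry=20000, sex=2, entry_date=entry)
        path = hazard_path(synth_rt, d, 120)
        oracle = calendar_walk_hazard(synth_rt, 20000, 2, entry, 120)
        assert np.array_equal(path, oracle)
        jan1_index = day_of_date(1996, 1, 1) - entry  # day u hits Jan 1 at u = idx
        assert path[jan1_index - 2] != path[jan1_index + 1]

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_demographics_match_calendar_walk(self, synth_rt, seed):
        rng = np.random.default_rng(seed)
        d = Demographics(
            age_at_entry=int(rng.integers(10000, 30000)),
            sex=int(rng.integers(1, 3)),
            entry_date=int(rng.integers(11000, 14000)),
        )
        path = hazard_path(synth_rt, d, 900)
        assert np.array_equal(
            path, calendar_walk_hazard(synth_rt, d.age_at_entry, d.sex, d.entry_date, 900)
        )

    def test_run_count_bounded_by_breakpoints(self, synth_rt):
        d = Demographics(age_at_entry=20100, sex=1, entry_date=11700)
        horizon = 3652
        path = hazard_path(synth_rt, d, horizon)
        runs = 1 + int((np.diff(path) != 0).sum())
        assert runs <= int(np.ceil(horizon / 365)) * 2 + 2

    def test_ages_beyond_table_clamp(self):
        rt = make_flat_ratetable(1e-4, ages=(0, 90))
        d = Demographics(age_at_entry=int(89.9 * DAYS_PER_YEAR), sex=1, entry_date=12000)
        with pytest.warns(UserWarning, match="clamped"):
            path = hazard_path(rt, d, 1200)
        assert np.all(path == 1e-4)

    def test_year_outside_table_raises(self, synth_rt):
        d = Demographics(age_at_entry=20000, sex=1, entry_date=0)  # 1960
        with pytest.raises(RateTableError, match="outside table"):
            hazard_path(synth_rt, d, 10)


class TestPopSurvival:
    def test_time_zero_is_one(self, const_rt):
        d = Demographics(age_at_entry=20000, sex=1, entry_date=12000)
        assert pop_survival(const_rt, d, 0) == 1.0

    def test_constant_hazard_closed_form(self, const_rt):
        d = Demographics(age_at_entry=20000, sex=2, entry_date=12000)
        assert pop_survival(const_rt, d, 730) == pytest.approx(
            np.exp(-1e-4 * 730), rel=1e-12
        )

    def test_birthday_example_matches_direct_summation(self):
        ages = np.arange(0, 111)
        years = np.arange(1985, 2015)
        h1, h2 = 1e-4, 3e-4
        hz = np.full((2, len(ages), len(years)), h1)
        hz[:, 61:, :] = h2
        rt = RateTable(ages=ages, years=years, hazard=hz)
        age_days = int(np.floor(60 * DAYS_PER_YEAR))
        d = Demographics(age_at_entry=age_days, sex=1, entry_date=12000)
        expected = np.exp(-np.sum(hazard_path(rt, d, 400)))
        brute = np.exp(
            -sum(calendar_walk_hazard(rt, age_days, 1, 12000, 400))
        )
        assert pop_survival(rt, d, 400) == pytest.approx(brute, rel=1e-12)
        assert expected == pytest.approx(brute, rel=1e-12)

    def test_multiplicative_over_abutting_intervals(self, synth_rt):
        d = Demographics(age_at_entry=22000, sex=1, entry_date=12345)
        t1, t2 = 700, 1800
        s1 = pop_survival(synth_rt, d, t1)
        s2 = pop_survival(synth_rt, d, t2)
        cond = np.exp(-hazard_path(synth_rt, d, t2)[t1:].sum())
        assert s1 * cond == pytest.approx(s2, abs=1e-12)

    def test_non_increasing(self, synth_rt):
        d = Demographics(age_at_entry=25000, sex=2, entry_date=13000)
        path = hazard_path(synth_rt, d, 1000)
        surv = np.exp(-np.cumsum(path))
        assert np.all(np.diff(surv) <= 0)
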