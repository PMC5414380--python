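import numpy as np
import pytest

from netsurv import (
    ScenarioConfig,
    calibrate_baseline,
    draw_cohort,
    run_experiment,
    scenario_preset,
)
from netsurv.simulate import HORIZON_DAYS, _draw

from .conftest import make_flat_ratetable


class TestDrawCohort:
    def test_zero_population_hazard_makes_worlds_equal(self, zero_rt):
        cfg = ScenarioConfig(n=500, lambda_e0=2e-4)
        real, hyp = draw_cohort(cfg, zero_rt, np.random.default_rng(0))
        assert np.array_equal(real.time, hyp.time)
        assert np.array_equal(real.status, hyp.status)

    def test_disease_time_marginal_is_exponential(self, zero_rt):
        lam = 2e-4
        cfg = ScenarioConfig(n=10000, lambda_e0=lam)
        _, hyp = draw_cohort(cfg, zero_rt, np.random.default_rng(1))
        p_hat = hyp.status.mean()
        p_true = 1 - np.exp(-HORIZON_DAYS * lam)
        se = np.sqrt(p_true * (1 - p_true) / cfg.n)
        assert abs(p_hat - p_true) < 3 * se

    def test_same_seed_bit_identical(self, synth_rt):
        cfg = scenario_preset("null_62", n=200)
        a_real, a_hyp = draw_cohort(cfg, synth_rt, np.random.default_rng(42))
        b_real, b_hyp = draw_cohort(cfg, synth_rt, np.random.default_rng(42))
        assert np.array_equal(a_real.time, b_real.time)
        assert np.array_equal(a_real.age_at_entry, b_real.age_at_entry)
        assert np.array_equal(a_hyp.status, b_hyp.status)

    def test_real_world_has_at_least_as_many_deaths(self, synth_rt):
        cfg = scenario_preset("null_62", n=400)
        for seed in range(3):
            real, hyp = draw_cohort(cfg, synth_rt, np.random.default_rng(seed))
            assert real.status.sum() >= hyp.status.sum()
            assert np.all(real.time <= hyp.time)

    def test_population_death_proportion_of_default_table(self, synth_rt):
        # shipped table level: 45-75 cohort accumulates ~0.23 population-death
        # probability over ten years (chosen so that ~62% of deaths are excess
        # when half the cohort dies overall)
        cfg = ScenarioConfig(n=8000, lambda_e0=1e-9)
        real, _ = draw_cohort(cfg, synth_rt, np.random.default_rng(4))
        assert 0.18 < real.status.mean() < 0.30

    def test_excess_death_share_matches_design(self, synth_rt):
        for name, lo, hi in [("null_62", 0.57, 0.67), ("null_93", 0.90, 0.97)]:
            cfg = scenario_preset(name, n=4000)
            real, hyp, H, W, excess = _draw(
                cfg, synth_rt, np.random.default_rng(5)
            )
            died = real.status == 1
            assert 0.45 < died.mean() < 0.55
            assert lo < excess[died].mean() < hi

    def test_nonproportional_switch(self, zero_rt):
        # beta jumping 0 -> large at 5 years concentrates the group-1
        # excess deaths after the switch
        cfg = ScenarioConfig(n=4000, lambda_e0=5e-5, nonprop=(0.0, 2.0, 1826))
        real, _ = draw_cohort(cfg, zero_rt, np.random.default_rng(6))
        late = real.time > 1826
        d1 = real.status[(real.group == 1) & late].mean()
        d0 = real.status[(real.group == 0) & late].mean()
        assert d1 > d0 + 0.1


class TestCalibration:
    def test_zero_hazard_closed_form(self, zero_rt):
        cfg = ScenarioConfig(n=1000)
        lam = calibrate_baseline(cfg, zero_rt, target_death_prop=0.5,
                                 n_cal=8000)
        closed = -np.log(1 - 0.5) / HORIZON_DAYS
        assert lam == pytest.approx(closed, rel=0.08)

    def test_validation_on_fresh_seed(self, synth_rt):
        cfg = ScenarioConfig(n=1000)
        lam = calibrate_baseline(cfg, synth_rt, target_death_prop=0.5,
                                 n_cal=8000)
        check = ScenarioConfig(n=8000, lambda_e0=lam)
        real, _ = draw_cohort(check, synth_rt, np.random.default_rng(777))
        assert abs(real.status.mean() - 0.5) < 0.025

    def test_monotone_in_target(self, zero_rt):
        cfg = ScenarioConfig(n=1000)
        lo = calibrate_baseline(cfg, zero_rt, target_death_prop=0.3, n_cal=4000)
        hi = calibrate_baseline(cfg, zero_rt, target_death_prop=0.7, n_cal=4000)
        assert hi > lo


class TestRunExperiment:
    def test_single_replicate_rejection_is_binary(self, synth_rt):
        cfg = scenario_preset("null_62", n=150)
        s = run_experiment(cfg, synth_rt, methods=["LRh"], seed=3, reps=1)
        assert s.rejection["LRh"] in (0.0, 1.0)

    def test_summary_reproducible(self, synth_rt):
        cfg = scenario_preset("null_62", n=150)
        a = run_experiment(cfg, synth_rt, methods=["LRt", "LRh"], seed=9, reps=3)
        b = run_experiment(cfg, synth_rt, methods=["LRt", "LRh"], seed=9, reps=3)
        assert a.to_dict() == b.to_dict()
        assert np.array_equal(a.pvalues["LRt"], b.pvalues["LRt"])

    def test_unknown_method_rejected(self, synth_rt):
        cfg = scenario_preset("null_62")
        with pytest.raises(ValueError, match="unknown method"):
            run_experiment(cfg, synth_rt, methods=["Cox"], seed=0, reps=1)

    def test_empty_methods_rejected(self, synth_rt):
        with pytest.raises(ValueError, match="nonempty"):
            run_experiment(scenario_preset("null_62"), synth_rt, methods=[],
                           seed=0, reps=1)


class TestConfig:
    def test_yaml_roundtrip(self, tmp_path):
        cfg = scenario_preset("power_strat5", n=123, nonprop=(0.5, -0.5, 1826))
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == cfg

    def test_invalid_values_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(lambda_e0=0)
        with pytest.raises(ValueError):
            ScenarioConfig(p_male=1.5)
        with pytest.raises(ValueError):
            ScenarioConfig(group_source="nope")

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError, match="unknown preset"):
            scenario_preset("table7")
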