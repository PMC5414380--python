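"""Competing-risks simulator and Monte-Carlo size/power experiments.

Cohorts are generated under the additive decomposition
``lambda_O = lambda_E + lambda_P`` by drawing the latent disease time
(exponential excess hazard, optionally covariate- and time-dependent), the
latent population time (by inverting each individual's cumulative population
hazard on the daily grid), and administrative censoring at ten years, then
taking minima.  Both the real-world data (all-cause, no cause labels) and the
hypothetical-world data (disease time only) are returned, so the log-rank
type test can be benchmarked against the classical log-rank test that would
be available if causes of death were known.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import yaml

from ._calendar import DAYS_PER_YEAR, day_of_date
from .cohort import Cohort
from .logrank import chi2_pvalue, logrank, rs_diff_from_processes
from .models import fit_fam
from .processes import _aggregate
from .ratetable import RateTable, hazard_path_matrix

__all__ = [
    "ScenarioConfig",
    "SimSummary",
    "draw_cohort",
    "calibrate_baseline",
    "run_experiment",
    "scenario_preset",
    "PRESETS",
]

ALL_METHODS = ("LRt", "LRt-str", "fAM", "LRh", "LRh-str")

HORIZON_DAYS = 3652  # ten years at 365.241 days/year, integer grid


@dataclass
class ScenarioConfig:
    """Design of one simulation scenario.

    Ages are drawn from a mixture of two uniforms (more weight on the older
    half, mimicking a typical patient population); sex is Bernoulli; calendar
    year of entry is uniform.  The excess hazard of individual i is

        lambda_E,i = lambda_e0 * exp(beta_group * x_i + beta_stratum * s_i
                                     + age_slope * (age_i - mean age))

    constant in time unless ``nonprop`` specifies a group effect switching
    value at ``switch_day`` (crossing-hazards designs).
    """

    n: int = 1000
    reps: int = 5000
    age_low: float = 45.0
    age_mid: float = 60.0
    age_high: float = 75.0
    age_weight_upper: float = 2 / 3
    p_male: float = 0.5
    year_low: int = 1990
    year_high: int = 2000
    lambda_e0: float = 1.1e-4            # per day; calibrate_baseline sets this
    group_source: str = "independent"    # "independent" | "sex"
    group_levels: int = 2
    group_balanced: bool = True          # imbalanced: top level w.p. 0.9
    beta_group: float = 0.0              # per level code
    stratum_source: Optional[str] = None  # None | "independent" | "age"
    stratum_levels: int = 2
    stratum_balanced: bool = True
    beta_stratum: float = 0.0
    age_band_years: float = 10.0         # stratum width when stratum_source="age"
    age_slope: float = 0.0               # per year of (centered) age
    nonprop: Optional[tuple] = None      # (beta_early, beta_late, switch_day)
    horizon_days: int = HORIZON_DAYS

    def __post_init__(self):
        if not (0 <= self.p_male <= 1 and 0 <= self.age_weight_upper <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.lambda_e0 <= 0:
            raise ValueError("lambda_e0 must be > 0")
        if self.horizon_days <= 0:
            raise ValueError("horizon must be > 0")
        if self.group_source not in ("independent", "sex"):
            raise ValueError(f"unknown group_source {self.group_source!r}")
        if self.stratum_source not in (None, "independent", "age"):
            raise ValueError(f"unknown stratum_source {self.stratum_source!r}")

    def to_yaml(self, path) -> None:
        d = asdict(self)
        if d["nonprop"] is not None:
            d["nonprop"] = list(d["nonprop"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if d.get("nonprop") is not None:
            d["nonprop"] = tuple(d["nonprop"])
        return cls(**d)

    @property
    def mean_age(self) -> float:
        w = self.age_weight_upper
        return (1 - w) * (self.age_low + self.age_mid) / 2 + w * (
            self.age_mid + self.age_high
        ) / 2


@dataclass
class SimSummary:
    """Monte-Carlo summary of one scenario x method set."""

    rejection: dict
    alpha: float
    reps: int
    seed: int
    n: int
    overall_death_prop: float
    excess_death_prop: float      # among real-world deaths: T_E < T_P
    observed_excess_prop: float   # among hypothetical-world deaths: seen in real world
    p_correlation: dict
    n_nonconverged: int
    pvalues: dict = field(repr=False, default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rejection": self.rejection,
            "alpha": self.alpha,
            "reps": self.reps,
            "seed": self.seed,
            "n": self.n,
            "overall_death_prop": self.overall_death_prop,
            "excess_death_prop": self.excess_death_prop,
            "observed_excess_prop": self.observed_excess_prop,
            "p_correlation": self.p_correlation,
            "n_nonconverged": self.n_nonconverged,
        }


# ---------------------------------------------------------------------------
# cohort generation


def _draw_covariate(rng, n, levels, balanced):
    if balanced:
        return rng.integers(0, levels, size=n)
    if levels != 2:
        raise ValueError("imbalanced covariates are binary (top level w.p. 0.9)")
    return (rng.random(n) < 0.9).astype(int)


def _linear_predictor(cfg, x, s, age_years, period=None):
    lin = cfg.beta_stratum * s + cfg.age_slope * (age_years - cfg.mean_age)
    if cfg.nonprop is None:
        return lin + cfg.beta_group * x
    beta_early, beta_late, _ = cfg.nonprop
    beta = beta_early if period == "early" else beta_late
    return lin + beta * x


def _draw_latent_excess(cfg, rng, x, s, age_years):
    """Latent disease death times (continuous days)."""
    e = rng.exponential(size=len(x))
    if cfg.nonprop is None:
        lam = cfg.lambda_e0 * np.exp(_linear_predictor(cfg, x, s, age_years))
        return e / lam
    _, _, switch = cfg.nonprop
    lam1 = cfg.lambda_e0 * np.exp(_linear_predictor(cfg, x, s, age_years, "early"))
    lam2 = cfg.lambda_e0 * np.exp(_linear_predictor(cfg, x, s, age_years, "late"))
    cum_switch = lam1 * switch
    t = np.where(e < cum_switch, e / lam1, switch + (e - cum_switch) / lam2)
    return t


def _draw_demographics(cfg: ScenarioConfig, rng: np.random.Generator):
    """Demographics and covariates for one replicate."""
    n = cfg.n
    upper = rng.random(n) < cfg.age_weight_upper
    age_years = np.where(
        upper,
        rng.uniform(cfg.age_mid, cfg.age_high, size=n),
        rng.uniform(cfg.age_low, cfg.age_mid, size=n),
    )
    age_days = np.round(age_years * DAYS_PER_YEAR).astype("int64")
    sex = np.where(rng.random(n) < cfg.p_male, 1, 2)
    year = rng.integers(cfg.year_low, cfg.year_high + 1, size=n)
    day_in_year = rng.integers(0, 365, size=n)
    entry = np.array([day_of_date(y) for y in range(cfg.year_low, cfg.year_high + 1)])
    entry_date = entry[year - cfg.year_low] + day_in_year

    if cfg.group_source == "sex":
        x = sex - 1
    else:
        x = _draw_covariate(rng, n, cfg.group_levels, cfg.group_balanced)
    if cfg.stratum_source is None:
        s = np.zeros(n, dtype=int)
        stratum = None
    elif cfg.stratum_source == "independent":
        s = _draw_covariate(rng, n, cfg.stratum_levels, cfg.stratum_balanced)
        stratum = s
    else:  # age bands: strata from bands, the age effect itself stays continuous
        s = np.clip(
            np.floor((age_years - cfg.age_low) / cfg.age_band_years).astype(int),
            0,
            None,
        )
        stratum = s
    return age_years, age_days, sex, entry_date, x, s, stratum


def _latent_population_days(C: np.ndarray, ep: np.ndarray, horizon: int):
    """Invert each row's cumulative hazard at an Exp(1) draw (daily grid)."""
    tp_idx = (C < ep[:, None]).sum(axis=1) + 1      # first day C >= draw
    return np.where(tp_idx <= horizon, tp_idx, np.iinfo("int64").max)


def _draw(cfg: ScenarioConfig, rt: RateTable, rng: np.random.Generator):
    """One replicate; returns cohorts plus reusable daily matrices."""
    age_years, age_days, sex, entry_date, x, s, stratum = _draw_demographics(cfg, rng)
    horizon = cfg.horizon_days
    te = _draw_latent_excess(cfg, rng, x, s, age_years)
    te_days = np.maximum(np.ceil(te), 1).astype("int64")

    H = hazard_path_matrix(rt, age_days, sex, entry_date, horizon)
    C = np.cumsum(H, axis=1)
    tp_days = _latent_population_days(C, rng.exponential(size=cfg.n), horizon)

    latent_min = np.minimum(te_days, tp_days)
    t_real = np.minimum(latent_min, horizon)
    d_real = (latent_min <= horizon).astype(int)
    excess = te_days <= tp_days                      # disease beat other causes

    t_hyp = np.minimum(te_days, horizon)
    d_hyp = (te_days <= horizon).astype(int)

    real = Cohort(
        time=t_real, status=d_real, age_at_entry=age_days, sex=sex,
        entry_date=entry_date, group=x, stratum=stratum,
    )
    hyp = Cohort(
        time=t_hyp, status=d_hyp, age_at_entry=age_days, sex=sex,
        entry_date=entry_date, group=x, stratum=stratum,
    )
    W = np.exp(C)
    return real, hyp, H, W, excess


def draw_cohort(cfg: ScenarioConfig, rt: RateTable, rng):
    """Draw one paired (real-world, hypothetical-world) cohort."""
    real, hyp, _, _, _ = _draw(cfg, rt, rng)
    return real, hyp


# ---------------------------------------------------------------------------
# baseline calibration


def calibrate_baseline(
    cfg: ScenarioConfig,
    rt: RateTable,
    target_death_prop: float = 0.5,
    tol: float = 0.01,
    n_cal: int = 10000,
    seed: int = 987654321,
) -> float:
    """Baseline excess hazard giving a target overall death proportion.

    Bisection on ``lambda_e0`` against the Monte-Carlo proportion of
    individuals dying (any cause) before the censoring horizon, with common
    random numbers across candidate values (fixed calibration seed).
    """
    rng = np.random.default_rng(seed)
    cal_cfg = ScenarioConfig(**{**asdict(cfg), "n": n_cal})
    age_years, age_days, sex, entry_date, x, s, _ = _draw_demographics(cal_cfg, rng)
    e_e = rng.exponential(size=n_cal)
    H = hazard_path_matrix(rt, age_days, sex, entry_date, cfg.horizon_days)
    C = np.cumsum(H, axis=1)
    tp_days = _latent_population_days(C, rng.exponential(size=n_cal), cfg.horizon_days)

    def death_prop(lam0):
        trial = ScenarioConfig(**{**asdict(cfg), "lambda_e0": lam0})
        if trial.nonprop is None:
            lam = lam0 * np.exp(_linear_predictor(trial, x, s, age_years))
            te = e_e / lam
        else:
            _, _, switch = trial.nonprop
            l1 = lam0 * np.exp(_linear_predictor(trial, x, s, age_years, "early"))
            l2 = lam0 * np.exp(_linear_predictor(trial, x, s, age_years, "late"))
            te = np.where(
                e_e < l1 * switch, e_e / l1, switch + (e_e - l1 * switch) / l2
            )
        te_days = np.maximum(np.ceil(te), 1)
        return float(
            (np.minimum(te_days, tp_days) <= cfg.horizon_days).mean()
        )

    lo, hi = 1e-8, 5e-2
    if not (death_prop(lo) < target_death_prop < death_prop(hi)):
        raise ValueError("target death proportion not bracketed")
    for _ in range(60):
        mid = np.sqrt(lo * hi)
        p = death_prop(mid)
        if abs(p - target_death_prop) <= tol:
            return float(mid)
        if p < target_death_prop:
            lo = mid
        else:
            hi = mid
    return float(mid)


# ---------------------------------------------------------------------------
# experiments


def _fam_pvalue(real: Cohort, rt: RateTable, levels: int):
    """Wald-type p-value for the group effect in the additive model."""
    x = real.group
    if levels == 2:
        X = x[:, None].astype(float)
    else:
        X = (x[:, None] == np.arange(1, levels)[None, :]).astype(float)
    fit = fit_fam(real, rt, x=X, names=[f"g{i}" for i in range(1, levels)])
    if not fit.converged:
        return np.nan
    J = len(fit.xi)
    beta = fit.beta
    covb = fit.cov[J:, J:]
    try:
        U, df, p = chi2_pvalue(beta, (covb + covb.T) / 2)
    except (ValueError, np.linalg.LinAlgError):
        return np.nan
    return p


def run_experiment(
    cfg: ScenarioConfig,
    rt: RateTable,
    methods: Sequence[str] = ("LRt", "LRh"),
    seed: int = 0,
    alpha: float = 0.05,
    reps: Optional[int] = None,
) -> SimSummary:
    """Monte-Carlo rejection rates of the selected tests under ``cfg``.

    Per-replicate seeds are spawned deterministically from ``seed``; the
    summary is bit-reproducible from (config, seed).
    """
    methods = list(methods)
    if not methods:
        raise ValueError("methods must be nonempty")
    for m in methods:
        if m not in ALL_METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {ALL_METHODS}")
    reps = reps if reps is not None else cfg.reps
    streams = np.random.SeedSequence(seed).spawn(reps)
    pvals = {m: np.full(reps, np.nan) for m in methods}
    death_prop = np.zeros(reps)
    excess_prop = np.full(reps, np.nan)
    observed_prop = np.full(reps, np.nan)
    n_nonconv = 0
    levels = 2 if cfg.group_source == "sex" else cfg.group_levels

    for r in range(reps):
        rng = np.random.default_rng(streams[r])
        real, hyp, H, W, excess = _draw(cfg, rt, rng)
        died = real.status == 1
        death_prop[r] = died.mean()
        if died.any():
            excess_prop[r] = excess[died].mean()
        hyp_died = hyp.status == 1
        if hyp_died.any():
            observed_prop[r] = excess[hyp_died].mean()
        if "LRt" in pvals or "LRt-str" in pvals:
            if "LRt" in pvals:
                wp = _aggregate(real, H, W, cfg.horizon_days, use_strata=False)
                pvals["LRt"][r] = rs_diff_from_processes(wp, real.n).p
            if "LRt-str" in pvals:
                wps = _aggregate(real, H, W, cfg.horizon_days, use_strata=True)
                pvals["LRt-str"][r] = rs_diff_from_processes(wps, real.n).p
        if "LRh" in pvals:
            pvals["LRh"][r] = logrank(hyp, tau=cfg.horizon_days).p
        if "LRh-str" in pvals:
            pvals["LRh-str"][r] = logrank(hyp, strata=True, tau=cfg.horizon_days).p
        if "fAM" in pvals:
            p = _fam_pvalue(real, rt, levels)
            if np.isnan(p):
                n_nonconv += 1
            pvals["fAM"][r] = p

    rejection = {
        m: float(np.nanmean(pvals[m] < alpha)) if np.isfinite(pvals[m]).any() else np.nan
        for m in methods
    }
    p_corr = {}
    for i, a in enumerate(methods):
        for b in methods[i + 1:]:
            ok = np.isfinite(pvals[a]) & np.isfinite(pvals[b])
            if ok.sum() >= 3 and np.std(pvals[a][ok]) > 0 and np.std(pvals[b][ok]) > 0:
                p_corr[f"{a}~{b}"] = float(np.corrcoef(pvals[a][ok], pvals[b][ok])[0, 1])
    return SimSummary(
        rejection=rejection,
        alpha=alpha,
        reps=reps,
        seed=seed,
        n=cfg.n,
        overall_death_prop=float(death_prop.mean()),
        excess_death_prop=float(np.nanmean(excess_prop)),
        observed_excess_prop=float(np.nanmean(observed_prop)),
        p_correlation=p_corr,
        n_nonconverged=n_nonconv,
        pvalues=pvals,
    )


# ---------------------------------------------------------------------------
# shipped scenario presets
#
# lambda_e0 values come from calibrate_baseline against the default synthetic
# rate table (target: half of the cohort dies within ten years); see
# docs/methods.md.  BETA_POWER is the default effect size for power runs.

# Effect size for power runs: chosen so the classical log-rank on
# hypothetical-world data has power ~0.8 at n=1000 with ~35% net mortality
# (mid-range power, so orderings between designs are visible)
BETA_POWER = 0.3

_PRESET_KW = {
    # ~60% of deaths due to excess hazard (patients aged 45-75)
    "null_62": dict(age_low=45, age_mid=60, age_high=75, lambda_e0=1.138e-4),
    # ~93% of deaths due to excess hazard (patients aged 25-55)
    "null_93": dict(age_low=25, age_mid=40, age_high=55, lambda_e0=1.735e-4),
    "power_62": dict(
        age_low=45, age_mid=60, age_high=75, lambda_e0=1.138e-4,
        beta_group=BETA_POWER,
    ),
    "power_93": dict(
        age_low=25, age_mid=40, age_high=55, lambda_e0=1.735e-4,
        beta_group=BETA_POWER,
    ),
    # stratification covariate with a strong (5x) effect
    "null_strat5": dict(
        age_low=45, age_mid=60, age_high=75, lambda_e0=4.61e-5,
        group_source="sex", stratum_source="independent",
        beta_stratum=5 * BETA_POWER,
    ),
    "power_strat5": dict(
        age_low=45, age_mid=60, age_high=75, lambda_e0=4.61e-5,
        group_source="sex", beta_group=BETA_POWER,
        stratum_source="independent", beta_stratum=5 * BETA_POWER,
    ),
    # continuous age effect on the excess hazard (ignored inhomogeneity);
    # slope scaled so the spread across the age range is 5x the group effect
    "null_inhom_age": dict(
        age_low=45, age_mid=60, age_high=75, lambda_e0=1.208e-4,
        group_source="sex", stratum_source="age", age_band_years=10.0,
        age_slope=5 * BETA_POWER / 30.0,
    ),
    "power_inhom_age": dict(
        age_low=45, age_mid=60, age_high=75, lambda_e0=1.208e-4,
        group_source="sex", beta_group=BETA_POWER,
        stratum_source="age", age_band_years=10.0,
        age_slope=5 * BETA_POWER / 30.0,
    ),
}

PRESETS = tuple(sorted(_PRESET_KW))


def scenario_preset(name: str, **overrides) -> ScenarioConfig:
    """Shipped scenario configurations (see PRESETS for names)."""
    if name not in _PRESET_KW:
        raise ValueError(f"unknown preset {name!r}; choose from {PRESETS}")
    kw = dict(_PRESET_KW[name])
    kw.update(overrides)
    return ScenarioConfig(**kw)
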