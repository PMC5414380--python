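# Methods

This note documents the statistical content of `netsurv`: the model, the
estimators and tests, the numerical conventions, what the simulator does and
does not emulate, and the design choices that were genuinely open.

## Model

For individual *i* the observable all-cause hazard is assumed to decompose
additively,

    λ_O,i(t) = λ_E,i(t) + λ_P,i(t),

where λ_P,i is the background ("population") hazard read from a mortality
table by sex, attained age and calendar year, treated as known, and λ_E,i is
the disease-attributable excess hazard.  Net survival is
S_E(t) = exp(−∫₀ᵗ λ_E).  The data are (T_i, δ_i) with
T_i = min(T̃_E,i, T̃_P,i, C_i) and no cause-of-death labels; the *hypothetical
world* data (T_E,i, δ_E,i) = (min(T̃_E,i, C_i), 1{T̃_E,i < C_i}) exist only in
simulation and provide the benchmark any real-world method can at best
approach.

## Rate tables and daily integration

- Internal hazard unit is **per day**; annual probabilities q convert via
  λ_d = −log(1−q)/365.241.
- One year of age is **365.241 days**.  Attained age uses completed years
  (floor); birthdays therefore follow the 365.241-day convention rather than
  true calendar leap handling, while calendar-year boundaries (January 1sts)
  follow the true Gregorian calendar.  The test-suite oracles use the same
  conventions, so exact numeric agreement with other implementations'
  leap-day micro-conventions is not claimed.
- Dates are integer days since 1960-01-01.
- An individual's hazard path is piecewise constant with breakpoints at
  January 1sts and birthdays; cumulative hazards integrate in **one-day
  steps**, the discretisation error being O(λ_P) per day.
- Ages beyond the last table row clamp to it (warning, not an error);
  calendar years outside the table raise — no extrapolation.

## Weighted processes and the log-rank type test

Each individual at risk on day u contributes weight w_i(u) = 1/S_P,i(u) to
the at-risk process, −w_i(u)·λ_P,i(u) to the daily compensator, and, on the
death day, w_i(T_i) to the event process.  The compensator accumulates on
the death day itself; a half-day correction was rejected as it is dominated
by the one-day integration error.  Event times are rounded to integer days
on ingestion; same-day increments are summed.  Days on which the pooled
weighted risk set is empty are skipped (indicator in the integrand), and the
Pohar Perme curve truncates (rather than errors) when the risk set empties
before τ.  The curve may locally exceed 1 when the compensator outweighs
observed events; this is inherited from the estimator itself.

The test statistic per group h is

    Z_h(τ) = Σ_u I(Ŷ_E,·(u) > 0) [dN̂_E,h(u) − (Ŷ_E,h(u)/Ŷ_E,·(u)) dN̂_E,·(u)],

τ defaulting to the largest observed time.  **Covariance**: the exact form
published for this test is not reproduced here; `netsurv` uses the
expected-form plug-in

    Σ̂_hj(τ) = Σ_u (δ_hj p̂_h(u) − p̂_h(u) p̂_j(u)) · Σ_i S_P,i(u)⁻² dN_i(u),

with p̂_h the weighted at-risk fractions — i.e. the classical martingale
log-rank covariance kernel applied to squared-weight event mass.  Two
properties motivated this choice: with S_P ≡ 1 it reduces *exactly* (to
machine precision) to the martingale-variance classical log-rank, and its
finite-sample adequacy is verified empirically by the null-size simulations
(rejection within three binomial standard errors of 0.05 in every shipped
null design).  Exact numeric agreement with other implementations of the
test is therefore not claimed.

The stratified version computes Z_s and Σ̂_s within each stratum and sums
over strata before forming U = Zᵀ Σ̂⁻¹ Z.  Strata with no events, or with
fewer than two groups present, carry no information about the contrast and
are dropped with a logged count of excluded individuals.  U is referred to
χ² with k−1 degrees of freedom; a numerically singular Σ̂ (relative
eigenvalue < 1e−10) falls back to the pseudo-inverse with the degrees of
freedom reduced to the rank.

The classical log-rank test offers two per-day covariance kernels:
`hypergeometric` (standard ties-corrected factor (Y−dN)/(Y−1), matching
survdiff-style implementations) and `martingale` (no ties factor, the exact
reduction target of the weighted test).

## Fully parametric additive model

λ_O(t,x) = λ_P(t,x) + λ_E0(t) e^{xβ} with λ_E0 piecewise constant on a day
grid (default: one interval covering the whole follow-up, matching the
constant-baseline simulations; e.g. `breakpoints=[365, 3652]` gives the
two-interval variant).  The log likelihood needs λ_P only at each death day;
the ∫λ_P term is parameter-free and dropped.  The baseline is parameterised
on the log scale (ξ_j = log λ_E0,j) to keep positivity unconstrained,
initialised at the crude event rate with β = 0.  Optimisation is BFGS with
analytic gradients followed by damped Newton steps on the
finite-difference observed information until the gradient max-norm falls
below 1e−6 (BFGS alone stalls at relative precision ~1e−5 on
log-likelihoods of magnitude ~10³).  The covariance is the inverse observed
information; a fit is flagged non-converged if the gradient norm stays
above 1e−4 or the information is not positive on the coefficient block —
this occurs when excess events are very scarce, and the simulator counts
(rather than fails on) such replicates.  The Wald test (asymptotically
equivalent to the score test at these sample sizes) is used on
coefficients; baseline parameters cannot be Wald-tested through that
interface.  Multi-group comparisons use the quadratic form over the k−1
dummy coefficients.

## Simulator

One replicate draws, independently per individual: age from a mixture of
two uniforms (default 45–60 w.p. 1/3, 60–75 w.p. 2/3 — more older
patients), sex Bernoulli(0.5), entry date uniform over 1990–2000; latent
disease time exponential with rate λ_E0·exp(linear predictor); latent
population time by inverting the individual's daily cumulative population
hazard at an Exp(1) draw; administrative censoring at 10 years (3652 days),
no earlier censoring.  Real world: minimum of the three.  Hypothetical
world: disease time censored at 10 years.  Nonproportional designs switch
the group coefficient at 5 years (the midpoint; the switch time was an open
choice).

**Synthetic rate table.**  Makeham–Gompertz per-day hazard
(a + b·e^{c·age})·improvement^(year−y₀), female cells scaled by 0.55,
defaults a = 7e−7, b = 1.9e−7, c = 0.092/year, improvement 0.99/year.  The
level was fixed, before any size/power run, so that with overall deaths
calibrated to ~50% the two shipped age designs yield ~62% and ~93% of
deaths due to the excess hazard — the two study conditions of interest.
This puts the pure population-death probability of the 45–75 cohort at
≈ 0.23 over ten years; a heavier table (e.g. 10-year population-death
probability 0.33) would push the excess share down to ≈ 0.45, so the two
constraints cannot be met simultaneously and the excess share was given
priority.

**Calibration.**  `calibrate_baseline` bisects λ_E0 against the Monte-Carlo
overall-death proportion (common random numbers, fixed calibration seed,
n = 10 000, tolerance 0.01).  Shipped presets carry the frozen results:
1.138e−4/day (62% design), 1.735e−4/day (93% design), 4.61e−5 and
1.208e−4/day for the stratum-effect and age-inhomogeneity designs.

**Effect sizes.**  The power-run group effect is β = 0.3, chosen so the
classical log-rank on hypothetical-world data has power ≈ 0.8 at n = 1000
given ~35% net mortality — mid-range power, so orderings between designs
remain visible (β = log 2 saturates every test at this sample size).
Stratum effects are 5× the group effect; the continuous age effect uses
slope 5β/(age range) per year, so its spread across the age distribution is
comparable to the 5× binary stratum effect.  Age-band strata come in
10y/5y/1y/6m/1m presets (3/6/30/60/360 strata).

**What the simulator does not emulate**: informative or staggered
censoring, frailty beyond the categorical/linear covariates above,
table-misspecification (the same table generates and analyses the data),
and non-exponential baseline excess hazards.  Passing size/power checks
therefore validate the estimators under the stated model, not robustness to
violations of it.

## Problem sizes

Monte-Carlo checks in the test suite use 120–300 replicates at n = 1000
(null sizes compared to 0.05 within three binomial standard errors *at the
replicate count actually run*); `scripts/acceptance.py` uses 400 replicates
for sizes and 150–200 for power orderings, and completes in about five
minutes on one CPU.  The exactness checks (reduction to the classical
log-rank at unit weights, 1e−12; brute-force per-day oracle on 4-subject
cohorts, 1e−9) are deterministic given their seeds.

## Known limitations

- No variance or confidence bands for the Pohar Perme curve (point
  estimate only); no Ederer I/II expected-survival estimators.
- No semi-parametric (EM) additive model, spline baselines, Cox fitting,
  weighted (Fleming–Harrington) log-rank variants, trend tests, or
  permutation p-values.
- The plug-in covariance of the weighted test is a documented design
  choice, validated by simulation, not a transcription of the published
  estimator.
- Sub-daily precision in the compensator integral (also unresolved in the
  wider literature for related estimators) is not pursued.
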