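# Methods

## The compartmental prevalence model

Adult smoking prevalence is modelled as one compartment fed by initiation
and drained by permanent cessation and smoker mortality:

    dπ/dt = λ − (θ + μ) π.

All three rates are annual per-capita proportions and are assumed constant
within a 6-year analysis period (7 years is also accepted, matching an
alternative historical periodisation).  The closed form

    π(t) = (π(0) − S) e^{−(θ+μ) t} + S,   S = λ/(θ+μ)

is evaluated exactly; `project` chains it across periods by using each
period's end value as the next period's anchor, which makes the path
continuous and, inside one period, identical to a single evaluation over
the whole span (the semigroup property, tested to 1e−12).  Time is
continuous in years with calendar years treated as integer offsets from the
period anchor (2013 → 2019 is t = 6).

Definitions worth keeping straight:

- **λ (initiation)** is *not* the 18-year-old smoking prevalence: it is the
  number of 18-year-old smokers divided by the entire adult population, so
  λ ≈ prev18 × (n_18 / n_adult) with a census ratio near 0.018.
  `prep.initiation_rate` / `prep.prev18_from_lambda` convert in both
  directions.
- **θ (cessation)** is the permanent quit rate, net of relapse.
- **μ (mortality)** is the overall smoker death rate, built as the
  population-weighted mean of age–gender–year stratum rates.

θ+μ = 0 has no steady state and is rejected; an explicit
`allow_degenerate` flag enables the linear-growth limit π(0) + λt (capped
at 1) for property tests only.

## Units and display

Internally everything is a proportion; files and reports use percent, with
`_pct`-suffixed CSV columns.  Reports round prevalence to two decimals,
percentage-point drops to one decimal, and shares to whole percents.

## Cessation-rate estimation

Within one period, λ and μ are fixed inputs and (π(0), θ) are estimated by
minimising Σ w_i (π_obs(t_i) − π(t_i; π0, θ))², with w_i = 1/se_i² when
every observation carries a positive survey SE and w_i = 1 otherwise.
Joint estimation of π(0) (rather than pinning it to the first observation)
is the default because it is robust to first-year sampling noise; a
`pin_pi0` option provides the pinned variant.

Numerics: a bounded trust-region least-squares solver (analytic Jacobian,
tolerances 1e−14) started from π0 = first observation and a θ multi-start
grid {0.01, 0.03, 0.05, 0.10} to guard against local minima; θ is
constrained to [0, 1).  A grid-search oracle test confirms the optimum on
random instances.  Bulk simulation tests use the single start θ = 0.03 for
speed — on these well-conditioned instances it reaches the same optimum,
and the oracle test covers correctness.

Inference: with inverse-variance weights the sampling variances are known,
so cov(π̂0, θ̂) = (JᵀWJ)⁻¹ from the weighted Jacobian at the optimum; with
uniform weights the covariance is scaled by the residual variance.  95% CIs
are Wald (θ̂ ± 1.96·SE) by default; a seeded parametric bootstrap
(percentile, default 1000 draws) is available for small-sample honesty.
At least 4 usable points are required per period; points flagged missing
(e.g. an incompatible final survey year) are simply excluded, so a 6-year
period may be fit on 5 points.

Under the study-like conditions (SE ≈ 0.25 pp, 6 annual points) the suite
verifies: exact recovery (≤1e−6) on noiseless data, median |θ̂ − θ| below
0.5 pp over 200 replicates, and 95% CI coverage within [88%, 100%] over
500 replicates.

## Random-effects meta-regression

Each period-by-survey estimate y_i (percent/year) is modelled as

    y_i ~ N(β0 + β1·I_NSDUH,i + β2·t_i + β3·I_last,i , v_i + τ²),

the classical random-effects meta-regression: v_i is the within-estimate
sampling variance recovered from the reported 95% CI
(((hi − lo)/(2·1.96))²) and τ² ≥ 0 a shared additive heterogeneity
variance.  The fit is maximum likelihood (not REML): for fixed τ² the
coefficients are the GLS solution, and the profiled likelihood is
maximised over τ² by bounded scalar search with an explicit boundary check
at τ² = 0.  Wald SEs come from (XᵀWX)⁻¹ with W = diag(1/(v_i+τ²)), normal
two-sided p-values, CIs β̂ ± 1.96·SE — no small-sample t correction, which
is what reproduces the published CI arithmetic.  On the eight published
rows the implementation matches R's `metafor::rma(..., method="ML")` to
all printed digits (kept as an independent cross-check in the test suite).

Time-index convention: `t_scale="period"` (default) uses the sequential
period index 1…5, with both surveys sharing the index of their calendar
period; `t_scale="year"` uses 6·(index−1).  The two are exact
reparameterisations (β2 scales by 6, all else invariant); the period-index
scaling is the one whose trend coefficient (≈0.52) matches the published
value (≈0.50), so it is the default.  Remaining ≈0.02 pp gaps to the
published coefficients are consistent with the published table rounding
estimates and CIs to one decimal while the original fit used unrounded
values.

The reduced model drops the survey-source term (it is far from
significant); the `trend_departure_test` helper returns β3 with its Wald CI
and p-value and leaves the α = 0.05 decision to the caller.

## Counterfactual decomposition

For a change from old-period rates (λ_o, θ_o) to new-period rates
(λ_n, θ_n), four end-of-horizon prevalences are computed from the same
starting level: (i) both old, (ii) both new, (iii) λ_o with θ_n, (iv) λ_n
with θ_o.  The excess drop (i) − (ii) is attributed one-at-a-time and
averaged over both substitution orders (a two-player Shapley split):

    pp_cessation = ½[((i)−(iii)) + ((iv)−(ii))],
    pp_initiation = ½[((i)−(iv)) + ((iii)−(ii))],

which is symmetric and exactly additive (pp_c + pp_i = excess, to machine
precision).  Fixed-order variants are exposed via `attribution=`.
Mortality travels with the cessation rate in the mixed scenarios — both
are smoker outflow — which coincides with holding μ fixed whenever the two
periods share a μ, as they nearly do here.  `share_recent` divides the
excess drop by the total drop from the starting level to scenario (ii);
shares are reported as absent (None), never 0/0, when the excess drop is
exactly zero.

With the printed recent-period inputs (π(2013) = 17.71%, old λ = 0.355%
back-solved from the 19.7% → 12.2% fall in 18-year-old prevalence, old
θ = 4.2%, new λ = 0.22%, new θ = 5.4%, μ = 0.83% back-solved from
SSP = 3.53%), the decomposition reproduces the 14.9%/13.3% counterfactual
2019 prevalences, a 1.6 pp excess drop and a ≈0.96 pp cessation
contribution; exact shares differ from pre-rounded headline arithmetic by
≤2 pp (e.g. 37% vs 1.6/4.4 = 36%).

## Synthetic-data generator

`synth.generate` emulates the observation process the estimators face:

- a true trajectory from the model under the scenario's period rates
  (defaults: five 6-year periods 1990–2019, θ rising 2.4 → 5.4 %/yr with
  an above-trend final step, λ falling 0.55 → 0.22 %/yr, μ = 0.83 %/yr,
  starting prevalence 26%);
- per survey, observations = truth + constant definition offset +
  N(0, se²), truncated to [0, 1] with a warning if truncation touches >1%
  of draws.  Defaults: NHIS-like SE 0.25 pp with 1996 and 2019 missing;
  NSDUH-like SE 0.20 pp, +5 pp offset (inside the observed 4.5–6 pp
  band), starting 2002.  These SEs are generator defaults chosen to make
  published-scale CI widths emerge, not claims about the surveys;
- census counts with a smooth 18-year-old share near 0.018, and a
  mortality table built from symmetric stratum factors with equal
  populations so its population-weighted mean equals each period's true μ
  exactly (round-trips through `overall_mortality` to 1e−10);
- survey-specific 18-year-old prevalence series consistent with each
  observed series: a series level-shifted by c obeys the same dynamics
  with effective initiation λ + (θ+μ)c, which is also why the
  broader-definition survey reports roughly twice the initiation rate.
  Without this consistency, fitting the offset survey with the base λ
  would bias θ̂ downward.

Seeding: one master seed, spawned into independent child streams per
survey; same seed → identical output, different seeds → same truth,
different noise.  Additive Gaussian noise is the default because it is
what the estimator's inverse-variance weights assume and how survey point
estimates are published.

What the generator does **not** emulate: survey design effects,
clustering, nonresponse weighting, age structure, reporting bias, or
serially correlated redesign artefacts.  Passing tests therefore show the
statistical machinery is correct under the stated observation model, not
that real survey series satisfy that model.

## Pipeline conventions

`run_pipeline` validates the configuration (file existence, contiguous
non-overlapping periods) before any computation, then runs
prep → estimate → metareg → project/decompose and writes
`estimates.csv`, `fit.json`, `trajectory.csv`, `decomposition.json` and
`summary.txt`.  Cells with fewer than 4 usable observations are skipped
with a log line (this is how the NSDUH-like survey contributes only its
three post-2001 periods).  The projection anchors at the fitted (not
observed) final-period end prevalence to avoid observation noise, extends
the final period's rates indefinitely, and the decomposition compares the
last two fitted periods over their 6-year horizon.  Re-running a config
reproduces byte-identical numeric outputs.

## Problem sizes used in the test suite

Simulation-based checks use 200 replicates (estimator recovery, end-to-end
trend/departure recovery), 400 (meta-regression coefficient recovery),
500 (CI coverage) and 1000 (noise-SD calibration); these sizes give
Monte-Carlo error comfortably below the tested margins while keeping the
suite fast.

## Known limitations

- The model is single-compartment: no age structure, cohorts, or explicit
  relapse (θ is net of relapse by definition).
- Projection uncertainty intervals are out of scope; only point
  trajectories are produced.
- The meta-regression treats the estimate-level variances as known; with
  eight points, τ² is weakly identified and frequently estimated at its
  boundary (0).
- Period-level λ and μ are simple means of annual values within the
  period, consistent with the constant-rate assumption of the closed form.
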