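# Methods

## Design

The package implements a two-stage interrupted time series (ITS) for daily
acute-care visit counts around an abrupt environmental event. The study
frame is three discontiguous November–January seasonal windows (2022–23,
2023–24, 2024–25; 276 days), an event date of 2025-01-07 inside the final
window, and post-event analysis windows of 7 and 14 days. Series are
indexed by exposure stratum (high / moderate / minimal, defined by distance
to event perimeters), care modality (outpatient / virtual), and cause
category (all-cause plus ICD-10 groups I00–I99, S00–T88, F01–F99, J00–J99).
Stage 1 learns each series' pre-event structure and predicts its
counterfactual post-event trajectory; stage 2 converts observed-minus-
expected contrasts into excess counts and percent changes with Monte Carlo
empirical confidence intervals (eCIs), pools strata, and scales to a target
population.

## Synthetic data generator

Real analyses of this kind run on restricted EHR extracts, so the generator
is the package's test bed. Daily counts are negative binomial,

    y ~ NB(mu, k),   Var = mu + mu^2/k,
    mu = baseline · weekday(dow) · exp(a·cos(2π(doy − peak)/365.25))
         · exp(Σ_j c_j (x_j − center_j)) · lift(t),

with `lift(t) ≡ 1` before the event. The exact counterfactual mean `mu0`
and lift of every cell-day are recorded as ground truth; expected window
excess `Σ mu0·(lift − 1)` is a seed-free closed form of the configuration.

Defaults (chosen once as plausible magnitudes for a large integrated health
system in coastal Southern California; they are synthetic, not observed):

| parameter | default | units / note |
|---|---|---|
| baseline rates | all-cause 400, respiratory 90, cardiovascular 60, neuropsychiatric 55, injury 50 | visits/day per stratum×modality cell |
| weekday multipliers | 1.15, 1.10, 1.05, 1.05, 1.00, 0.85, 0.80 (Mon–Sun) | mean exactly 1 |
| annual amplitude `a` | 0.2 (log scale), peak day-of-year 10 | winter-peaked |
| dispersion `k` | 10 | heavily overdispersed; `inf` = Poisson |
| meteorology | annual harmonic + AR(1) noise, φ = 0.7 | tmax/tmin °C, humidity %, wind m/s, radiation W/m² |
| wastewater | weekly lognormal, winter-peaked (flu amp 1.0, RSV 0.8, SARS-CoV-2 0.5; log-noise 0.2) | constant within ISO week |
| covariate effects `c_j` | tmax −0.01, wind +0.02, flu +0.10, RSV +0.06, SARS-CoV-2 +0.06 | per centred unit |

Geographies are planar constructions: fire perimeters are boxes sharing a
band, tracts are squares placed due north with their x-extent inside one
fire's, so each tract's minimum boundary distance is exactly its vertical
offset and requested exposure-class mixes are recoverable by construction.

What the generator does **not** emulate: individual members and enrollment
churn (counts are drawn at the cell-day level), spatial autocorrelation
between tracts, smoke-plume gradients distinct from distance, holiday-
specific care-seeking beyond a flag, multi-diagnosis encounters, and
reporting/backfill artifacts. Passing tests therefore demonstrate that the
estimator recovers known effects under realistic count noise, seasonality,
and covariate structure — not that it is robust to every idiosyncrasy of
real EHR streams.

## Stage 1: counterfactual learner

Features per date: seven day-of-week indicators, day-of-season index,
season index, holiday flag (Thanksgiving, Dec 24–25, Dec 31, Jan 1;
configurable), day-of-year, six daily meteorological covariates, and three
wastewater covariates forward-filled from weeks to days.

The learner is a residual-stacked hybrid. The base component is OLS on
weekday indicators, `K` annual harmonics of day-of-year, and the holiday
flag; the residual component is an XGBoost regressor on the full feature
matrix fit to the base's residuals; the prediction is their sum, clipped at
zero (clipped days are flagged). Candidates — base settings × residual
settings (including "none") — are scored by mean RMSE over rolling-origin
folds whose validation blocks tile the tail of the pre-period, each fold
training only on earlier days; the argmin (ties to grid order) is refit on
the full pre-period. No post-event outcome enters any stage, and the
persisted fit is byte-identical whether or not post-event outcomes exist.

Two base terms — a within-season linear trend and per-season intercepts —
are grid options, off by default. Both are estimated from the head of each
season and extrapolated into its tail, exactly where the post-event window
sits; under the generator's stationary-within-season conditions they
inflate 7-day-window prediction error SD from about 7% to about 15% of the
expected count without reducing bias. Cross-validation can still select
them (the default grid includes a trend variant) for data with genuine
drift.

Covariates deliberately enter only through the boosted component: weekly
viral levels are strong, nearly harmonic regressors, and adding them
linearly to the base alongside the harmonics produced collinear designs
with worse out-of-window error. Defaults for the boosted trees are gently
regularized (depth 2, 100 rounds, learning rate 0.05, min child weight 20,
L2 = 10): with count noise this overdispersed, aggressive boosting
memorizes week-keyed noise and its leaf errors are shared by all seven days
of a post-event week.

## Stage 2: excess, eCIs, pooling

Daily excess is `y_t − ŷ_t`; percent change divides by `ŷ_t` (undefined
and flagged when `ŷ_t = 0`). Window excess sums the daily differences (so
additivity is exact in floating point), and window percent change is
predicted-weighted, `100·Σ(y−ŷ)/Σŷ`, not a mean of daily percentages.

The 95% eCI for each window uses a seeded Monte Carlo (default 1,000
iterations). Each iteration builds a perturbed counterfactual
`ŷ*_t = ŷ_t · (1 + r*_t)` from circular-block-bootstrapped residuals
(default block 7 days) and recomputes excess and percent change; bounds are
the 2.5th/97.5th percentiles over iterations. Three choices matter:

- **Relative, not additive, perturbation.** Count noise scales with the
  mean, so adding raw pre-period residuals understates post-event
  uncertainty whenever the event lifts the level (analytically ~83%
  coverage for a 41% lift at dispersion 10). Relative residuals restore
  nominal coverage; `residual_scale="absolute"` retains the additive
  scheme. All pre-period residuals exactly zero still collapse the
  interval to the point estimate.
- **Out-of-fold residuals.** In-sample residuals are shrunk by the boosted
  component and make intervals anticonservative; the default pool is the
  selected candidate's rolling-origin validation residuals (147 days under
  the 7-fold, min-train-100 study layout). `residual_source="insample"` is
  available.
- **Finite-pool corrections.** The pool holds only ~20 exchangeable
   7-day blocks, so raw extreme quantiles of the draws are near-order-
  statistics with ~30% run-to-run scale noise. Two standard corrections,
  both on by default and switchable: a variance-corrected smoothed
  bootstrap (Silverman bandwidth) that continuizes the draw tails without
  changing their spread, and a Student-t/normal quantile ratio at
  df = (pool size / block length) − 1 for the pool's scale underestimate.

Percent-scale bounds recompute the percent change within each iteration
(`(y − ŷ*)/ŷ*`); the convexity of `1/ŷ*` stretches the upper bound, which
matches the right skew of the count-noise-driven estimator.

Pooling sums member strata's observed, predicted, and per-iteration draws
(draws pair by iteration), so pooled excess is exactly additive and the
pooled eCI reflects cross-stratum dependence on the shared calendar.
Population scaling divides excess by an enrollment coverage fraction in
(0, 1]. The difference-in-differences comparator is deliberately naive:
`(log T_post − log T_pre) − (log C_post − log C_pre)` on period totals,
with a leave-one-day-out jackknife SE — it ignores seasonality and
covariates by design, to quantify the bias the counterfactual ITS avoids.

## Replicated studies and problem sizes

`studies.py` pins the evidence base: a headline-analogue recovery study
(41% lift on high-stratum virtual respiratory visits, baseline 300/day,
dispersion 10; 200 seeds; n_iter 200), a null-calibration study (same
generator, no lift; 500 seeds; n_iter 1000, the estimation default), and a
DiD-discordance study (treated/control winter amplitudes 0.8 vs 0.0 on the
log scale, dispersion 500, no covariate effects, true effect 0%; 200
seeds). Typical results: recovery median within ~1.5 points of 41% with
~90–94% eCI coverage of the truth; null mean within ±1 point of 0 with
~5–6% zero-exclusion; discordance (DiD biased beyond 2 jackknife SE while
the ITS eCI covers 0) in ~85–90% of seeds. Each study runs in tens of
seconds to a few minutes on one CPU; `scripts/acceptance.py` re-runs them
at 120/300/120 seeds. The studies' learner is the pinned single-candidate
hybrid with 7-fold rolling-origin CV (min train 100 days), chosen to
maximize the residual calibration pool over the 251-day pre-period.

## Numerical conventions and degenerate inputs

Seeds: every stochastic component derives its seed from a master seed by
hashing a stage label (CRC32, < 2^31), so adding a stage never shifts
another's randomness; identical configuration and seed reproduce every
artifact bit-identically (report timings excluded). Ties in CV go to grid
order. Negative raw predictions clip to zero and are flagged. Zero
predictions make percent change undefined (NaN, flagged) while excess is
still reported. Overlapping seasonal windows, an event date outside the
final window, empty perimeter sets, malformed ICD codes, unassigned visit
records, constant-zero outcomes, empty pre-periods, and fold layouts
without enough days all raise typed errors. Exposure distances follow the
strict convention: < threshold is high, exactly the threshold is not.

## Limitations

The hybridization of the base and boosted components, the cross-validation
scheme, and the Monte Carlo mechanism are one defensible reading of this
family of designs, not a replication of any specific production pipeline.
Stratum series are modelled independently in stage 1; only stage 2 couples
them. The eCI quantifies residual-scale uncertainty around a fixed selected
model — hyperparameter-selection uncertainty is not propagated. County
scaling assumes the enrolled population's effect transfers
proportionally to the uncovered population. The DiD comparator is
intentionally minimal and should not be used as a primary estimator.
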