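# Methods

This note documents the models, the synthetic data-generating process,
numerical choices, and the validation design, in the package's own
terms.

## Exposure construction

Dryness is expressed as a percentile in [0, 100] relative to a
climatology (100 = driest).  Default category bins follow the U.S.
Drought Monitor percentile convention: D0 at the 70th–80th dryness
percentile, D1 80–90, D2 90–95, D3 95–98, D4 ≥ 98, with the wet
categories mirrored (W0 20–30 down to W4 < 2) and NEUTRAL between.
Bins are a configuration table; intervals are half-open `[lo, hi)` with
the top bin closed at 100, so every percentile maps to exactly one
category and drier percentiles never map to wetter categories.

A drought **event** is a maximal run of D1–D4 months of length ≥ 2 (the
`min_duration` parameter; D0 and wet/neutral months break runs).
Within an event, **Cumulative Drought Intensity** is the running sum of
monthly severity scores (D1 = 1 … D4 = 4), reset implicitly because it
is event-scoped.  The **phase split** assigns the worsening phase to all
months whose running CDI is ≤ 50% of the event total, the improving
phase to the rest.  Two edge rules are fixed deliberately:

* *inclusive at equality* — a month landing exactly on 50% is
  worsening, which makes even-length palindromic severity profiles
  split exactly at their midpoint;
* *first-month fallback* — if the first month alone exceeds 50% of the
  total (e.g. severities [4, 1, 1]), it is still worsening, so both
  phases are non-empty for every event.

Monthly labels cross the phase with the month's own severity bucket
(D1–D2 moderate-to-severe, D3–D4 severe-to-exceptional).  Months in wet
categories outside events are WET; everything else — NEUTRAL, D0, and
D1–D4 months in sub-threshold runs — is NONE.  The six labels partition
all county-months; the unit tests verify the partition and check the
whole rule against an independent brute-force enumeration on every
severity sequence of length ≤ 6 and on random series.

When only a raw index is available (positive = drier), dryness
percentiles can be derived by mid-rank empirical ranking within each
(county, calendar-month) climatology cell; with ~19 years per cell this
is coarse but unbiased.

## Stage one: county negative-binomial GAM

For one county, outcome and stratum, monthly deaths follow NB2 with a
log link, a log-population offset, exposure dummies (reference NONE),
three meteorological-season dummies (DJF reference), and unpenalised
B-spline smooths for monthly mean temperature and the panel time index
(1..T).  Choices worth recording:

* **Basis.** A spline with `k` knots is realised as a B-spline basis
  with exactly `k` columns: degree min(3, k), interior knots at
  quantiles, first basis column dropped for identifiability next to the
  intercept.  Unpenalised bases make the AIC parameter count literal
  (all regression columns + 1 for dispersion), which keeps the knot
  search reproducible without committing to any penalisation scheme.
  A numerically constant covariate collapses its basis to zero columns
  and is flagged; remaining collinear columns are dropped
  earliest-first by a Gram–Schmidt rank sweep.
* **Dispersion.** One NB2 dispersion per county model, estimated by
  profile likelihood: the scalar profile over log(alpha) in
  [1e-8, 50] is maximised (bounded Brent), with an IRLS GLM fit at each
  candidate alpha.  This is robust at the Poisson boundary, where joint
  Newton iterations have a singular information matrix; the upper bound
  caps boundary drift.  Coefficient covariance is the GLM
  observed-information covariance at the profiled alpha (dispersion
  uncertainty is not propagated into coefficient SEs; with the small
  dispersions typical of monthly death counts the effect is minor).
* **Knot search.** All 16 combinations of k_temp ∈ {2,3,4,5} ×
  k_time ∈ {3,4,5,6} are fitted; the lowest-AIC converged fit wins,
  with ties broken by smaller k_temp + k_time, then smaller k_temp.
  County-best fits feed the meta-analysis; the modal pair across
  counties is reported as a diagnostic only (a config option pins a
  fixed pair, e.g. the modal 4-4, everywhere).  Counties where no
  combination converges (e.g. all-zero counts) are excluded and logged.

## Stage two: random-effects pooling

County log-IRRs y_i with standard errors s_i follow
y_i ~ N(mu, s_i² + tau²).  tau² is estimated by REML (bounded scalar
optimisation of the restricted likelihood, boundary at zero checked
explicitly); DerSimonian–Laird is available as a method switch.  mu is
the inverse-variance weighted mean at the estimated tau²; the 95% CI is
the Wald interval on the log scale, exponentiated.  The implementation
is cross-checked in the tests against a fine-grid restricted-likelihood
maximisation and against `metafor::rma` in R (agreement to ≤ 1e-5).

Inclusion: estimates with SE > 2 on the log-IRR scale are excluded as
unstable (boundary inclusive: SE = 2 stays).  The threshold applies to
the coefficient scale because that is what stage one estimates and the
only scale on which a fixed bound is meaningful.  A population-minimum
rule (≥ 10,000 / 25,000 / 30,000) is available for sensitivity
analysis.  Pooled effects carry `n_included / n_eligible` coverage with
a strict over-85% label; the eligibility denominator is every county
present in the input panel.

## Effect measures

The baseline rate alpha of a stratum is deaths per million persons per
month over the stratum's NONE-labelled person-time — NONE is the
model's reference exposure, and per-month is the panel's natural time
unit.  ARD = alpha·(IRR − 1)/IRR; the map is strictly increasing in IRR
for alpha > 0, so CI endpoints transform exactly (no delta-method
approximation needed), and it inverts as IRR = alpha/(alpha − ARD).

## Descriptive summary conventions

Person-based percentages (age, sex, urbanicity) use the outcome's death
total as denominator.  Exposure-category death percentages use the sum
of the six category counts — in the national source data a small set of
deaths falls outside the categorised set, and the published percentages
are only reproducible with this denominator.  County-month frequencies
use total county-months.  Percentages are rounded to two decimals; one
published frequency cell (WET, 6.4759%) appears truncated to 6.47 where
round-to-nearest gives 6.48.

## Synthetic data-generating process

Per county, a stationary standard-Gaussian AR(1) latent series z_t
(persistence `eddi_ar1`, default 0.95, emulating the heavy smoothing of
a 12-month index) is mapped to dryness percentiles via
`100·Phi(clim_shift + clim_stretch·z_t)`.  With the default shift 0 /
stretch 1 the percentiles are uniform and each category's long-run
occupancy equals its bin width.  `calibrate_exposure_mix` solves shift
and stretch from the Gaussian quantile relations of the wet (30th),
drought-onset (80th) and severe-onset (95th) boundaries so the
simulated period is *drier than its reference climatology* and the
county-month exposure mix lands within ±5 points of the observed
national distribution (~56% none, ~28% moderate-to-severe, ~10%
severe-to-exceptional, ~6.5% wet); the solution is verified by
simulation and degenerate targets are rejected.

Populations are log-normal across counties (default median 25,000,
log-sd 1.4 — a heavy lower tail so small-county instability arises
naturally), constant over time.  Temperature is a county-specific
sinusoid (period 12, amplitude U(6, 12) °C around a N(12, 4) mean) plus
N(0, 1.5) noise.  Counts are NB2 with mean = population × baseline rate
× exp(season + quadratic temperature effect + linear trend + planted
log-IRR of the month's label).  Defaults: baseline 7.16 (firearm) and
6.43 (nonfirearm) deaths per million adults per month (implied by the
published national IRR/ARD pairs), planted IRRs equal to the national
pooled estimates (e.g. 1.109 for worsening severe-to-exceptional,
firearm), a mild seasonal pattern peaking in spring (+8% vs winter), a
+10% log-linear trend over the panel, and NB2 dispersion alpha = 0.05 —
monthly county death counts are near-Poisson, and substantially larger
alphas would imply variance far beyond anything vital-statistics
series show.  Optional strata (age, sex) thin the total counts
multinomially with fixed fraction × rate-multiplier weights, so stratum
counts sum exactly to totals.

What the generator does *not* emulate: spatial correlation of drought
across counties (each county's driver is independent), population
trends or migration, within-year population change, reporting artefacts,
and any real geography.  Passing recovery tests therefore demonstrate
correctness of the estimation machinery under the assumed model, not
robustness to spatial confounding or misclassification.

## Validation design and known limitations

The recovery experiments (acceptance tests) run 50 replicates of 200
counties × 228 months with stage one at the fixed 4-4 knot pair, and
pool the worsening severe-to-exceptional firearm coefficient across
counties; planted-null runs check CI coverage of 1.  These panels use
large county populations (log-normal median 2·10⁶, log-sd 0.3), a
deliberate choice: they test that the two-stage estimator is correct in
its information-rich regime, where its assumptions hold.

The rare-count regime is different, and honestly so.  A county's
log-IRR MLE has finite-sample bias of order −(1 + alpha·mu)/(2·M),
where M is the expected death count during exposed months; and when M
is well below 1 (small counties), counties with zero exposed-period
deaths produce unstable, huge-SE estimates that the SE ≤ 2 rule then
excludes — a selection that biases the pooled estimate of a rare
exposure category upward (we measure ≈ +0.14 on the log scale at a
25,000-median population law with 200 counties).  This is a property of
SE-filtered two-stage pooling of rare counts, not of this
implementation; it is mitigated in practice by the dominance of large
counties in inverse-variance weights and by pooling thousands rather
than hundreds of counties, but users analysing small-population panels
should treat pooled IRRs for rare categories with caution and compare
the SE rule against the population-threshold sensitivity rule.

Computation sizes throughout (test-suite replicate counts, county
counts, the single-combination knot grid in the recovery runs) are the
package's validation choices, balancing Monte-Carlo precision against
the cost of ~10,000 county fits per experiment.
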