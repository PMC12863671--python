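# Methods

## Model and assumptions

The estimator treats a chronic disease as an irreversible illness-death
process: healthy → diseased (incidence *i*), healthy → dead (*m*₀),
diseased → dead (*m*₁), no recovery. Prevalence along a birth cohort then
satisfies (∂t + ∂a) p = (1 − p)[i − p(m₁ − m₀)], and with the general
mortality m = p·m₁ + (1 − p)·m₀ and MRR = m₁/m₀ the incidence is

    i = D/(1 − p) + m·p·(MRR − 1)/(1 + p·(MRR − 1)),

with D the Lexis-direction derivative of prevalence. The inversion is exact
algebra; all estimation error enters through the inputs (fitted p and D,
tabulated m, fitted MRR). Implicit assumptions: the disease is chronic
(no remission), the aggregated prevalence reflects the population at risk,
and the external MRR age profile transfers to the target population up to a
global calibration factor (probed by the ±15% scenarios).

The general mortality of one population is combined with an MRR estimated
in another; the implied (m₀, m₁) split is internally consistent by
construction (`mortality_split` inverts m = p·m₁ + (1 − p)·m₀ under
m₁ = MRR·m₀), and the inversion formula is applied exactly as written.

## Estimation pipeline and parameters

* **Prevalence fit** (`prevalence_model`): empirical logits of
  cases/population are regressed per sex on a natural cubic spline in age
  (truncated-power basis, knots at the observed 5-year group midpoints,
  natural boundary conditions, no penalty) with calendar year entering
  linearly plus year × spline interaction columns (switchable,
  `year_by_spline`). Weights are the binomial working weights N·p(1 − p);
  with the large denominators typical of claims data this coincides with a
  binomial GLM to high order and gives closed-form SE(η). Dispersion is
  estimated from the weighted residuals by default, so SE(η) absorbs
  overdispersion and lack of fit; a `fixed` option pins it at the nominal
  binomial value (under which exact weighted-LS identities such as the
  duplicate-rows 1/√2 SE shrinkage hold). Strata at exactly 0% or 100%
  are continuity-corrected to (cases + 0.5)/(N + 1) with a warning. The age
  covariate of a group [lo, hi] is its midpoint (lo + hi + 1)/2; an
  open-ended group is assigned lo + 2.5. Prediction is refused outside
  [min midpoint − 2.5, max midpoint + 2.5].
* **Lexis derivative**: D(a) = [p(t + h, a + h) − p(t − h, a − h)]/(2h) on
  the fitted surface, default h = 4 years so that with anchor year 2013 the
  stencil touches 2009 and 2017. An analytic mode
  D = p(1 − p)(∂t η + ∂a η) from the basis derivatives is available and
  agrees with the finite difference to ~1e−3 on smooth fits. The finite
  difference carries an O(h²) bias of roughly (hk)²/6 for locally
  exponential prevalence (growth rate k) — about 2–4% here — which is a
  property of the estimator, not of its implementation.
* **MRR fit** (`mrr_model`): ordinary least squares of log(stratum MRR) on
  the stratum age midpoint, per sex; reported per-sex and pooled adjusted
  R². Unweighted by default (matching a plain regression on reported
  ratios); an expected-deaths-weighted option is provided and is the right
  choice when raw counts are available, because Poisson noise on log(MRR)
  has variance ≈ 1/deaths and the unweighted normal-theory coefficient SEs
  understate the sampling spread when sparse strata sit at high-leverage
  ages (measured z-score sd ≈ 1.8 unweighted vs ≈ 1.2 weighted on the
  default scenario). The calibration factor multiplies predictions after
  back-transformation and round-trips exactly.
* **Bootstrap** (`bootstrap_engine`, default B = 5,000, quantiles
  0.025/0.975, type-7 interpolation): per replicate, one independent N(0,1)
  deviate per prevalence linear-predictor evaluation point (anchor point
  and both stencil points, per support age and sex) scaled by SE(η), and
  independent deviates for each sex's (α, β) scaled by their SEs; no
  coefficient covariance term and no cross-age correlation — a deliberately
  simple, slightly conservative reading that widens rather than narrows
  intervals. Mortality is fixed. Replicates with perturbed prevalence
  outside [0, 1) or non-finite incidence are excluded from the quantiles
  with a logged count (the logit parameterisation makes this essentially
  impossible in practice, but the guard keeps the exclusion rule auditable).
  One master seed spawns named substreams (prevalence, MRR), so different
  calibration factors consume identical draws.
* **Negative incidence** from noisy inputs is preserved and flagged, never
  silently clipped; `floor_at_zero` is opt-in.
* **Support ages**: incidence is evaluated at the 5-year group midpoints
  (22.5 … 92.5), rows labelled 20–24 … 90+; `LexisGrid(midpoint_offset=0)`
  switches to group lower bounds.
* **Mortality lookup**: period rates are constant within a calendar year;
  the rate at integer age label a is attributed to a + 0.5 and interpolated
  linearly between midpoints.
* **Display spline** (`reporting`): a strictly interpolating natural cubic
  spline (scipy, natural boundary) carries median/percentile series to a
  fine grid; the band bounds are interpolated independently, so knot values
  are reproduced exactly while the band can be locally non-monotone between
  knots — a display convention, not an inference step. Rendering rounds
  half-up to three decimals per 1,000 person-years; missing values render
  as an explicit `NA`.

## Synthetic scenario (what it emulates, what it does not)

`synthetic_data` generates the three inputs from a known ground truth:
incidence i(a) = exp(b₀ + b₁·a), healthy mortality m₀(a) = c·exp(g·a)
(Gompertz), MRR(a) = exp(α + β·a), all time-constant; prevalence follows
from the cohort ODE with p(0) = 0 (4th-order fixed-step Runge–Kutta,
default step 0.1 yr in the public solver, 0.05 yr for truth tabulation).

Default scenario S1, chosen once to mimic a realistic heart-failure-like
configuration: male i(a) = exp(−12.6 + 0.11a), female
exp(−13.2 + 0.11a) — about 0.04 and 0.02 per 1,000 py at age 22.5 rising
to 88 and 49 per 1,000 py at 92.5, with the male excess throughout —
m₀ with c = 2e−5, g = 0.095 per year (adult all-cause-like schedule), and
MRR = exp(2.6 − 0.012a) (≈ 8 at age 40 declining to ≈ 4.4 at 92.5, the
familiar decline of relative excess mortality with age). Under these rates
prevalence stays below 0.35 everywhere (≈ 0.20/0.11 male/female at 95), so
the logit scale is well behaved over the whole table.

Population scales, chosen once on realism grounds: 200,000 persons per
single year of age × sex × year for the prevalence denominators
(statutory-claims scale; binomial noise), and 25,000 per single age × sex
for the MRR source population (Nordic national-registry scale). MRR strata
use the diseased cohort's person-years: expected deaths E apply m₀ to
them, observed deaths are Poisson with the true excess (O ~ Poisson(E·MRR)).
Strata run 40–94: at younger ages the scenario's diseased population is so
small that expected deaths fall below ~1 and observed/expected ratios of 0
occur, which a log-scale fit cannot use — mirroring why registry MRR tables
are sparse at young ages. Strata with zero observed deaths are dropped with
a warning. The prevalence table covers closed 5-year groups 0–109 so the
±4-year derivative stencil at every support midpoint stays inside the
fitted surface. Mortality tables are noise-free (the pipeline treats
general mortality as fixed).

Not emulated: regional stratification, claims case-definition logic
(minimum-two-quarters rules, diagnosis-code selection), time-varying rates,
migration, and differential coverage of the insured population. Passing
recovery tests therefore demonstrates the estimator's correctness under the
model's own assumptions, not robustness to those real-data features.

## Numerical choices

Fixed-step RK4 for the cohort ODE (smooth scalar field; deterministic and
step-refinement-stable to <1e−6 at step 0.1 vs 0.01). Truncated-power
natural-spline columns are scaled by (knot range)⁻² for conditioning;
statsmodels' pinv-based WLS handles the remaining collinearity, and a rank
check raises on a genuinely singular design. Empirical quantiles use the
default linear interpolation between order statistics (type 7). The HMD
writer emits full `%.17g` precision so write/read round trips are
bit-exact. All stochastic components draw from `numpy` Generators seeded
via `SeedSequence` spawning, making every artifact a pure function of the
configured seeds.

## Problem sizes in the shipped checks

The test suite and the acceptance script run the estimator at the scale a
single desk machine handles comfortably: the coverage study uses 200
simulated datasets with B = 500 replicates (the bootstrap is vectorised
across replicates, so this takes seconds), while single-bundle runs use the
full B = 5,000 with all three calibration factors. Monte-Carlo checks state
tolerances derived from the replicate spread (e.g. the B-stability check
bounds median differences by 4× the combined standard error of a sample
median, 1.2533·σ/√B) rather than fixed percentages, so they are calibrated
to the uncertainty actually present.

## Known limitations

* The finite-difference Lexis derivative has an O(h²) bias (~4% here at the
  youngest ages, where the derivative term dominates the incidence); the
  bootstrap quantifies parameter uncertainty only and does not see this
  bias. With the default scenario it is small relative to interval widths.
* Independent-per-point perturbation ignores the smoothing correlation of
  the fitted surface; intervals are somewhat conservative (measured
  age-70 coverage ≈ 100% at nominal 95%).
* The MRR coefficient perturbation draws intercept and slope independently,
  omitting their (negative) covariance; another mild conservatism.
* Unweighted log-MRR regression understates coefficient uncertainty under
  strongly heteroscedastic stratum counts (see above); prefer the weighted
  option when counts are reported.
* Aggregation attributes a 5-year group to its midpoint; with exponentially
  rising rates this contributes a small (<1%) convexity bias.
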