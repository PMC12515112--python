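# Methods

This note documents the statistical models, their assumptions, the
synthetic-data generator, and the numerical and design choices made in
`cesdemog`.

## Data model and selection filters

The unit record is one capture: ring id, species, scheme, site, year,
within-season visit, and age class (`A` adult / `J` juvenile). A site
belongs to exactly one scheme. Selection proceeds in three passes, each
logged record-by-record in a `SelectionReport`:

1. **Site-year coverage.** Let `V` be the modal maximum number of
   visits per site-year within the scheme (ties broken upward). A
   site-year is kept when it has at least `ceil(2/3 V)` distinct
   visits and at least `ceil(1/4 V)` in each half of the season (first
   half = visits `1..ceil(V/2)`). A site is kept when at least 5 of
   its years survive.
2. **Species counts.** Within a retained site-year, a species needs at
   least 2 adults and 2 juveniles.
3. **Population size.** A scheme-species population is analyzed when
   its mean number of distinct individuals per active year is at least
   50 (boundary inclusive).

Thresholds are exact rational comparisons (`Fraction`), so boundary
cases like a mean of exactly 50 are deterministic.

## Step 1a: survival (transient CJS)

Capture histories collapse to annual detections of adults (a bird's
juvenile-year capture does not start its history; multi-site birds are
assigned to their first site and flagged). The likelihood, conditional
on first capture at occasion `f`, is a two-component mixture: with
probability `1 - tau` the bird is a transient (never seen again); with
probability `tau` it is a resident following a standard CJS process
with annual survival `phi_t` (shared across sites) and site-specific
recapture probability `p_s`. The never-seen-again tail uses the chi
recursion `chi_T = 1`, `chi_t = (1 - phi_t) + phi_t (1 - p_s)
chi_{t+1}`. This mixture is algebraically identical to a
time-since-marking model whose first-interval survival is
`tau * phi_t` (verified history-by-history in the tests).

Numerics: histories are aggregated to sufficient statistics (site,
first, last, number of detections) with counts, so one likelihood
evaluation is a few vectorized array operations regardless of the
number of birds. Parameters are optimized on the logit scale with
L-BFGS-B from several seeded starts; standard errors come from the
numerically differentiated Hessian via the delta method. Birds first
captured in the final year carry no information and are dropped (and
counted). Estimated probabilities are floored at 1e-12 inside logs.

Two filters follow: sites whose estimated recapture probability falls
outside `[0.10, 0.90]` are excluded (boundary values retained) and the
model refitted once without them; annual survival estimates are kept
only where the SE lies strictly inside `(0.01, 0.25)` — too small
indicates a degenerate boundary estimate, too large an uninformative
one.

## Step 1b: annual indices

**Productivity** is modeled as juveniles out of all captures per
site-year with a logit-link binomial GLM on site and year and a
quasi-binomial dispersion; the annual estimate is the inverse logit of
(intercept + mean site effect + year effect) with a delta-method SE.
The dispersion `c-hat = pearson_chi2 / df_resid` is computed
explicitly and the model refitted with that fixed scale, because
statsmodels' `scale="X2"` shortcut mis-scales the covariance for
two-column binomial responses (it loses the per-cell trial counts); a
regression test pins the SE to the pooled binomial information bound.

**Abundance** is a log-link quasi-Poisson GLM of distinct adults per
site-year on site and year. The index is `exp(gamma_t)` with the first
year as reference (`x_1 = 1`, SE 0); growth rates depend only on
ratios, so the reference choice is immaterial downstream.

Species with `c-hat >= 4` in either model (strict inequality keeps
values below 4) are dropped from the scheme. A saturated model (no
residual df) has undefined dispersion and passes.

## Step 2: growth regression

For each population, the annual growth rate `r_t = log(1 + (x_{t+1} -
x_t)/x_t) = log(x_{t+1}/x_t)` is regressed on z-scaled (mean 0, sample
SD 1) survival over `t -> t+1` and z-scaled productivity of year `t`,
with weights `1 / ((SE_phi + SE_rho + SE_x)/3)^2`. An interval enters
only if all upstream filters passed and all three SEs are finite
(individual SEs may be 0 — the abundance reference year — but the mean
must be positive; this is required for the reference year to be usable
at all). At least 4 year-pairs are required; exactly collinear
predictors raise an error rather than returning an arbitrary solution.

## Step 3: weighted mixed models

The per-population slopes are stacked long (one row per population and
measure) and analyzed with Gaussian LMMs in which row `k` has known
residual variance `sigma^2 / w_k`, `w_k = 1/SE_k^2`:

* **A**: `coefficient ~ measure`, random intercepts species + scheme;
* **B**: `coefficient ~ measure * mean_temperature`, random intercept
  species (temperature is scheme-level);
* **C**: `coefficient ~ measure * migration + measure * habitat`,
  random intercepts species + scheme.

Reference levels: productivity, long-distance, forest. No Python
library exposes this weighting convention for mixed models, so the
REML machinery is implemented in `cesdemog.lmm`: the variance ratios
`gamma_j = sigma_j^2 / sigma^2` are profiled out and optimized on the
log scale (floor `exp(-30)`, treated as a boundary zero), and
`sigma^2` and the fixed effects then have closed forms. Satterthwaite
degrees of freedom use the numerically differentiated REML information
matrix. The implementation is validated in the test suite against
R's `lme4`/`lmerTest` (estimates and SEs to ~1e-6; dfs to ~0.1%;
variance components to the default `lmer` optimizer tolerance — with a
tightened `bobyqa` stop the two optima agree to ~12 digits).

Model B's raw temperature main effect is strongly correlated with its
interaction (the predictors are not centered, matching the model as
specified); the fit logs a collinearity warning but drops nothing.

## Synthetic-data generator

`simulate_multischeme` generates capture tables with known truth. Per
site and year, a Poisson number of new adults arrives with rate
`lambda_{s,t} = exp(log mean + site effect + year effect)`; each is a
resident with probability `tau`, residents survive with `phi_t` and
are recaptured with `p_s`. Juveniles are independent Poisson draws
with mean `rho_t/(1 - rho_t)` times the *expected* adult captures
`E[C_{s,t}]` (recursion `M_{t+1} = (M_t + tau lambda_t) phi_t`,
`E[C] = lambda + p M`). Independence from the realized adult count is
deliberate: two independent Poissons make the juvenile share binomial
given the total, so the productivity model is correctly specified with
unit dispersion. The generator does **not** emulate: within-season
timing, age-dependent survival beyond the transient effect, movement
between sites, observation effort gaps, or trend-driven year effects
(all year effects default to zero, so true abundance ratios follow the
expected-capture recursion).

`simulate_coefficient_table` skips steps 1–2 and draws the step-3
input table directly: `coefficient = mu(fixed effects) + b_species +
b_scheme + residual_sd * SE_k * N(0,1)` with `SE_k` uniform, so the
weighted LMM is exactly correctly specified — used for recovery and
type-I calibration studies.

Determinism: every stochastic routine takes an explicit seed; scheme
`i` uses stream `seed + i`; per-population optimizer seeds are derived
with CRC32 of `scheme/species` modulo `2^31 - 1`.

## Validation problem sizes

The acceptance layer (both `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses sizes chosen by this package as its own
reference designs: a 30-site, 12-year single-scheme recovery design
(`phi = 0.55`, `tau = 0.7`, `p in [0.3, 0.6]`, ~10 new adults per
site-year), and 240-row coefficient tables (20 species x 6 schemes x 2
measures, intercept 0.061, survival effect 0.019, random SDs 0.02).
Recovery criteria are evaluated with standard Monte-Carlo conventions:
CI coverage over interval-replicates; per-interval bias averaged over
replicates; index accuracy on replicate-averaged estimates (a single
replicate's abundance ratios share the reference-year's sampling error,
so per-replicate bounds would measure the design, not the estimator);
fixed-effect bias compared to the empirical SD across replicates.

## Limitations

* Apparent survival confounds mortality with permanent emigration, as
  in any CJS analysis without dead recoveries.
* Step 2 ignores estimation error correlation between `x_t` appearing
  in both `r_{t-1}` and `r_t`, and treats the z-scaled predictors as
  fixed; both follow the stated method.
* The step-2 weight (inverse squared *mean* of three SEs on different
  scales) is a pragmatic precision proxy, not a variance law.
* The weighted LMM treats the step-2 SEs as known; uncertainty in the
  SEs themselves is not propagated.
* The index GLMs assume effort is truly constant within the selected
  site-years; the selection filters enforce this only at the visit
  level.
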