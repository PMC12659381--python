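# Methods

## Model structure

The package projects excess NCD mortality as the difference between two
simulated death streams: a *crisis* arm in which treatment coverage
drops to scenario-specific levels after war onset, and a
*counterfactual* arm that keeps pre-war coverage throughout.  Both arms
run on a monthly grid whose months span the 7th of one calendar month
to the 6th of the next, matching the analysis periods (war onset
7 October 2023 = month 285 from the January 2000 origin; a four-month
"to date" sub-period; two three-month projection sub-periods).

Three disease mechanisms are modelled:

* **chronic** (stroke, CKD on haemodialysis, cancers): monthly incident
  cohorts enter at time-since-onset τ = 0 and die with probability
  `q(τ,t) = c_t q_T(τ) + (1 − c_t) q_U(τ)` each month — coverage mixes
  the treated/untreated probabilities *every* month, not once at onset;
* **cvd_acute** (ischaemic heart disease): an immediate acute
  case-fatality `c μ_acute,T + (1 − c) μ_acute,U` applies in the onset
  month; acute survivors enter the chronic ledger under post-acute
  hazards, i.e. hazards fitted to survival curves that were first
  divided by (1 − μ_acute);
* **prevalent_pool** (type-1 diabetes): a fixed pool is exposed from war
  onset with no new entrants and τ counted from exposure start.  This is
  adequate because the pool's hazards are configured time-constant
  (exponential), so the unknown true onset times are irrelevant.
  Baseline DM1 mortality is taken as zero (insulin coverage pre-war is
  near universal), so its counterfactual arm contributes almost nothing.

Cohorts are retired once τ exceeds `tau_max` (default: the burn-in
length, 285 months, since no upper tracking limit is inherent to the
model; configurable).

## Hazard families and units

Four candidate families are supported, parameterised in per-month
units: exponential (rate λ), Weibull (shape, scale), log-normal (μ, σ
on log-months) and log-logistic (α months, β).  The log-normal hazard
is the standard form φ(z)/(σ τ (1 − Φ(z))) with z = (ln τ − μ)/σ, which
is the unique form consistent with log-normal survival via
μ(τ) = −d ln S/dτ (a consistency the test suite checks by finite
differences).  Monthly death probabilities are exact:
`q(τ) = 1 − exp(log S(τ+1) − log S(τ))`, evaluated in log space so deep
tails do not lose precision; a quadrature test confirms
`q = 1 − exp(−∫ μ)` to 1e−8 across families.

Config files must declare the time unit of every hazard parameter set
(`per_month` or `per_year`; no silent default).  Year-to-month
conversion: rates ÷ 12, time scales × 12, log-normal μ + ln 12; the
conversion is idempotent on per-month input.

## Survival fitting

Literature survival points (proportion surviving at reported follow-up
times) are fitted by maximising an independent-binomial log-likelihood
Σ x ln S + (n − x) ln(1 − S) with x = round(n_eff × surviving); sources
without a cohort size get n_eff = 100.  Independence across time points
is an acknowledged approximation forced by the absence of
individual-level data.  Optimisation runs Nelder-Mead from a
deterministic multi-start grid on log-transformed positive parameters
(objective tolerance 1e−8) with a BFGS polish.  Families are ranked by
raw log-likelihood; AIC ranking is available (`selection="aic"`) but
off by default despite unequal parameter counts, because raw ML is the
selection rule of the original analysis.  Two-parameter families are
skipped (with a warning) when fewer than two distinct follow-up times
are available.  Where two alternative studies bound the survival curve,
both fits are stored (`bound="lower"/"upper"`) and mixed per run.

## Counterfactual baseline

Annual pre-war death counts per disease are fitted with a Poisson GLM
(log link, year as single predictor, centred at the first data year —
with two data points the fit interpolates exactly).  Forecasts are
deterministic point forecasts discretised to annual rate / 12 per
month; projection uncertainty is propagated only through coverage and
survival bounds, not the GLM.  Support utilities implement the 50/50
ischaemic/haemorrhagic stroke split and a plain population-ratio
scaling (e.g. West Bank to Gaza) applied at load time.

## Calibration

The calibration constant k scales raw mean incidence so the simulated
counterfactual matches the GLM forecast over the final 12 pre-war
months.  Because the *expected* ledger is linear in incidence, k is
computed from a single expectation-mode run (coverage at the baseline
range midpoint, bound weight 0.5) rather than by Monte-Carlo averaging;
this makes k deterministic and the post-calibration expectation match
exact.  A zero forecast yields k = 0 with a warning; zero simulated
deaths raise a calibration error.

## Uncertainty propagation and common random numbers

Per run and disease: one standard uniform per period is mapped onto
each arm's coverage range (baseline range for the counterfactual,
scenario range for the crisis arm), one Uniform(0,1) weight mixes
lower/upper survival bounds, incident cases are Poisson draws shared by
both arms, and per-month death draws (binomial per cohort-month) come
from generators keyed by (seed, scenario, disease, month) that both
arms share.  Consequences: (i) the burn-in segment is *identical*
across arms and is simulated once; (ii) if crisis ranges equal baseline
ranges the two arms coincide draw for draw, so per-run excess is
exactly zero — a property the tests exploit; (iii) the excess estimator
has much lower variance than independent arms would give.  Binomial
deaths per cohort-month are this implementation's choice (the source
analysis states only Poisson incidence sampling).  Expectation mode
replaces every draw by its mean (midpoint coverage, w = 0.5, expected
incidence, expected deaths) and is the deterministic oracle used for
calibration and testing.  Negative per-run excess is allowed and never
truncated.

Summaries report the mean and the empirical 2.5th/97.5th percentiles
(linear interpolation) across runs — the "95% interval" is read as the
central 95% range.  Age rows allocate each run's per-disease excess by
that disease's fixed pre-war age distribution of deaths (assumed
unchanged by the crisis) before percentiles are taken.  Because hazards
and coverage are age-independent, simulating the aggregate cohort and
allocating by age is exactly equivalent (in expectation) to simulating
each age stratum with incidence I × p_a, which the tests verify;
calibration is therefore per-disease rather than per-age.  Rounding
(half-up, thousands separators) happens only at table-writing time.

## Synthetic data generator

`generate_inputs(seed, profile)` emits a validated bundle plus ground
truth.  The `paper_like` profile mirrors the scale of the full
application: five disease groups (IHD with acute branch and log-normal
bounds, stroke log-logistic, CKD exponential with bounds, cancer
Weibull, DM1 prevalent pool of 2,500), nine age strata, six baseline
years (2017–2022) with a true log-linear slope of +0.02/yr and Poisson
noise, baseline coverage 0.90–1.00, nested scenario ranges (ceasefire ≥
status quo ≥ escalation pointwise) and 1000 runs.  Parameter magnitudes
were chosen so combined counterfactual mortality is a few hundred
deaths per month and per-disease excess is O(10–10³), the output scale
of the real application.  Untreated/treated hazard pairs share their
shape parameter within each family, which guarantees the untreated
hazard dominates at *all* τ.  The `small` profile (three diseases, one
per mechanism, 55-month grid from 2020) exists so stochastic tests run
in milliseconds.

The generator also provides survival observations drawn binomially
from the true curves (isotonic clipping repairs sampling inversions,
with a warning), and an analytic expectation oracle computed by
*onset-cohort accumulation* — survival products per entering cohort —
which is an independent implementation of the same model the engine
computes by a τ-indexed ledger recursion; the two agree to machine
precision, and the acceptance tests require 1%.

What the generator does **not** emulate: real digitised survival curves
(correlated extraction error, censoring), overdispersed or non-log-
linear baseline trends, age-dependent hazards or coverage, sex
structure, or the actual Gaza parameter values.  Passing tests
therefore demonstrate internal correctness and statistical calibration
of the machinery, not the accuracy of any real-world projection.

## Numerical and design choices

* All randomness flows from integer seed tuples through numpy
  `SeedSequence`/`PCG64`; identical bundle + seed gives bit-identical
  ledgers.
* Survival evaluation uses closed-form log-survival expressions (via
  `scipy.special.log_ndtr` for the normal tail) rather than generic
  distribution objects: the fitting loop and the τ-grids evaluate these
  millions of times.
* Problem sizes in the tests: the full stochastic pipeline (5 diseases ×
  3 scenarios × 1000 runs × 295 months) runs in about half a minute on
  one CPU; the test suite uses the small profile (20–200 runs) for
  stochastic properties and the paper_like profile in expectation mode
  for end-to-end fidelity.
* Relative-risk hooks φ_incidence and φ_cfr multiply incidence and both
  arms' death probabilities respectively; both default to 1 (all excess
  risk is attributed to lost treatment coverage).
* The engine is deliberately agnostic about which published application
  its parameters describe; everything empirical enters through the
  bundle.

## Known limitations

Binary treatment status (no partial adherence); no repeat acute CVD
events; no disease progression or incidence response to the crisis
beyond the φ hooks; no sex stratification; the DM1 pool ignores incident
cases; GLM forecast uncertainty is not propagated; the independent-
binomial likelihood understates extraction error in digitised curves.
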