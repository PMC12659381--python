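# ncd-excess

Scenario-based projection of excess mortality from non-communicable
diseases (NCDs) when a crisis disrupts health services.

When war or disaster interrupts treatment — dialysis sessions, insulin
supply, cardiac catheterisation, cancer surgery — people living with
chronic disease die earlier than they otherwise would.  This package
implements a discrete-time cohort microsimulation that quantifies those
*excess* deaths under alternative treatment-coverage scenarios, for
epidemiologists and humanitarian-health analysts.  It was built around
the modelling set-up used to project NCD mortality in the Gaza Strip
(war onset 7 October 2023, projection horizon to 6 August 2024), and is
driven either by user-supplied parameter tables or by a bundled
synthetic-data generator with known ground truth.

## The model

For each disease *u* and month *t* (dt = 1 month), excess deaths are

```
D_excess(u,t) = D_crisis(u,t) − D_base(u,t)
```

the difference between deaths simulated under wartime treatment
coverage and under pre-war (counterfactual) coverage.  Monthly incident
cohorts are simulated from January 2000; a cohort of age
*τ* (months since onset) dies each month with probability

```
q(τ,t) = c_t·q_T(τ) + (1 − c_t)·q_U(τ)
```

where `c_t` is treatment coverage and `q_T`, `q_U` are the treated and
untreated monthly death probabilities, `q(τ) = 1 − S(τ+1)/S(τ)`, derived
from parametric survival curves (exponential, Weibull, log-normal or
log-logistic) fitted by binomial maximum likelihood to cohort-study
survival points.  Cardiovascular disease adds an immediate acute
case-fatality risk `μ_acute` at first presentation; type-1 diabetes is a
fixed prevalent pool depleted from war onset.  Mean incidence is scaled
by a calibration constant *k* so that simulated counterfactual deaths
match a Poisson-GLM forecast of the pre-war annual death counts.
Uncertainty in coverage (uniform ranges per disease × period × scenario)
and in survival (lower/upper bound curves) is propagated over 1000
Monte-Carlo runs; paired crisis/counterfactual cohorts share random
draws, and results are reported as means with empirical 95% percentile
intervals by disease, age stratum and sub-period.

## Worked example

```python
from ncd_excess import generate_inputs, run_projection, summarise_runs, age_share

bundle, truth = generate_inputs(seed=1, profile="paper_like")
ledgers = run_projection(bundle, "status_quo", mode="stochastic", n_runs=500)
summary = summarise_runs(ledgers, bundle.grid,
                         {d.id: d.age_dist for d in bundle.diseases})

t = summary.table
row = t[(t.disease == "all") & (t.sub_period == "total") & (t.stratum == "all")].iloc[0]
print(f"total excess deaths: {row['mean']:.0f} ({row.pi_lo:.0f} to {row.pi_hi:.0f})")
print("share of excess deaths at ages >= 50:", age_share(summary, "50-59"), "%")
```

prints

```
total excess deaths: 2922 (2545 to 3426)
share of excess deaths at ages >= 50: 73 %
```

i.e. under the synthetic status-quo scenario the model projects ~2,900
excess NCD deaths (95% interval 2,545–3,426) over the ten analysis
months, about three quarters of them among people aged 50 and over.
The `ncd-excess` console script exposes the same pipeline
(`ncd-excess --synthetic --runs 200 --seed 1 --out out/`), and the
numbered scripts under `analysis/` walk through the stages — input
generation, survival fitting, baseline forecasting, scenario projection
and age-share summaries — writing their tables under `results/`.

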