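"""Synthetic input bundles with known ground truth.

The generator emits complete scenario bundles whose statistical structure
mirrors the study conditions: log-linear annual baseline death trends
with Poisson noise, survival observations drawn binomially from known
hazard families, uniform coverage ranges nested across scenarios
(ceasefire >= status quo >= escalation), near-universal pre-war coverage
and a fixed type-1-diabetes prevalent pool.  It is structural, not
empirical: no attempt is made to reproduce the Gaza parameter values.

Alongside each bundle it returns a :class:`GroundTruth` holding the true
parameters and analytic expectation-mode death trajectories, computed by
an onset-cohort accumulation that is independent of the engine's
time-indexed ledger recursion -- the oracle for end-to-end tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .baseline import AgeDistribution, BaselineSeries, fit_baseline_trend, forecast_monthly_baseline
from .cohort import (
    SCENARIOS,
    WAR_PERIODS,
    CoverageSchedule,
    DiseaseSpec,
    arm_death_prob_grid,
)
from .config_io import AGE_STRATA, PopulationTable, ScenarioBundle, TimeGrid
from .survival import AcuteRisk, HazardModel, survival_at

__all__ = ["GroundTruth", "generate_inputs", "generate_survival_observations"]


@dataclass
class GroundTruth:
    """True parameters and analytic expectations behind a synthetic bundle."""

    hazards: dict[str, dict[str, tuple[HazardModel, ...]]]
    incidence: dict[str, float]  # raw (pre-calibration) cases/month
    trends: dict[str, tuple[int, float, float]]  # disease -> (year0, log rate, slope/yr)
    pool_sizes: dict[str, float]
    coverage: CoverageSchedule
    calibration_k: dict[str, float] = field(default_factory=dict)
    #: scenario -> disease -> {"crisis": (M,), "counterfactual": (M,)}
    expected_monthly: dict[str, dict[str, dict[str, np.ndarray]]] = field(default_factory=dict)
    #: scenario -> disease -> sub-period -> expected excess deaths
    expected_excess: dict[str, dict[str, dict[str, float]]] = field(default_factory=dict)


def generate_survival_observations(
    true_model: HazardModel,
    times: Sequence[float],
    n_eff: int,
    rng: np.random.Generator,
    source: str = "synthetic",
    no_noise: bool = False,
):
    """Binomially noised survival points from a known hazard model.

    ``surviving_i = Binomial(n_eff, S_true(tau_i)) / n_eff``; any sampling
    inversions of monotonicity are removed by isotonic (running-minimum)
    clipping, with a warning when clipping was applied.
    """
    from .survival import SurvivalObservation

    times = list(times)
    if any(t <= 0 for t in times) or sorted(times) != times:
        raise ValueError("times must be sorted and strictly positive")
    if n_eff <= 0:
        raise ValueError(f"n_eff must be positive, got {n_eff}")
    s_true = np.asarray(survival_at(true_model, np.asarray(times, dtype=float)))
    if no_noise:
        s_obs = s_true.copy()
    else:
        s_obs = rng.binomial(n_eff, s_true) / n_eff
    clipped = np.minimum.accumulate(s_obs)
    if np.any(clipped < s_obs):
        warnings.warn("isotonic clipping applied to survival observations", stacklevel=2)
    return [
        SurvivalObservation(
            tau=float(t), surviving=float(s), n_eff=n_eff,
            arm=true_model.arm, source=source,
        )
        for t, s in zip(times, clipped)
    ]


# ---------------------------------------------------------------------------
# Disease catalogues
# ---------------------------------------------------------------------------

def _hm(family, params, arm, bound="point"):
    return HazardModel(family=family, params=params, arm=arm, bound=bound)


def _paper_like_catalogue():
    """Five disease groups at the output scale of the full application."""
    diseases = {
        "ihd": dict(
            kind="cvd_acute",
            acute=AcuteRisk(treated=0.05, untreated=0.30),
            hazards={
                "treated": (_hm("lognormal", {"mu": float(np.log(96.0)), "sigma": 1.5}, "treated"),),
                "untreated": (
                    _hm("lognormal", {"mu": float(np.log(18.0)), "sigma": 1.5}, "untreated", "lower"),
                    _hm("lognormal", {"mu": float(np.log(30.0)), "sigma": 1.5}, "untreated", "upper"),
                ),
            },
            incidence=160.0,
            monthly_baseline=150.0,
            age_shares=(0.001, 0.002, 0.007, 0.02, 0.06, 0.13, 0.20, 0.26, 0.32),
        ),
        "stroke": dict(
            kind="chronic",
            hazards={
                "treated": (_hm("loglogistic", {"alpha": 120.0, "beta": 0.9}, "treated"),),
                "untreated": (_hm("loglogistic", {"alpha": 30.0, "beta": 0.9}, "untreated"),),
            },
            incidence=60.0,
            monthly_baseline=40.0,
            age_shares=(0.002, 0.003, 0.01, 0.025, 0.06, 0.12, 0.20, 0.26, 0.32),
        ),
        "ckd": dict(
            kind="chronic",
            hazards={
                "treated": (_hm("exponential", {"rate": 0.004}, "treated"),),
                "untreated": (
                    _hm("exponential", {"rate": 0.20}, "untreated", "lower"),
                    _hm("exponential", {"rate": 0.10}, "untreated", "upper"),
                ),
            },
            incidence=8.0,
            monthly_baseline=15.0,
            age_shares=(0.01, 0.02, 0.04, 0.06, 0.10, 0.17, 0.22, 0.21, 0.17),
        ),
        "cancer": dict(
            kind="chronic",
            hazards={
                "treated": (_hm("weibull", {"shape": 0.8, "scale": 80.0}, "treated"),),
                "untreated": (_hm("weibull", {"shape": 0.8, "scale": 25.0}, "untreated"),),
            },
            incidence=70.0,
            monthly_baseline=60.0,
            age_shares=(0.005, 0.01, 0.025, 0.06, 0.12, 0.20, 0.24, 0.21, 0.13),
        ),
        "dm1": dict(
            kind="prevalent_pool",
            hazards={
                "treated": (_hm("exponential", {"rate": 0.0003}, "treated"),),
                "untreated": (_hm("exponential", {"rate": 0.05}, "untreated"),),
            },
            pool=2500.0,
            age_shares=(0.15, 0.25, 0.20, 0.15, 0.10, 0.07, 0.05, 0.02, 0.01),
        ),
    }
    coverage = {}
    for d in diseases:
        coverage[(d, "baseline", "baseline")] = (0.90, 1.00)
    to_date = {"ihd": (0.30, 0.50), "stroke": (0.30, 0.50), "ckd": (0.40, 0.60),
               "cancer": (0.15, 0.35), "dm1": (0.40, 0.60)}
    m1_3 = {
        "ceasefire": {"ihd": (0.50, 0.70), "stroke": (0.50, 0.70), "ckd": (0.55, 0.75),
                      "cancer": (0.20, 0.40), "dm1": (0.60, 0.80)},
        "status_quo": {"ihd": (0.35, 0.55), "stroke": (0.35, 0.55), "ckd": (0.45, 0.65),
                       "cancer": (0.15, 0.35), "dm1": (0.40, 0.60)},
        "escalation": {"ihd": (0.25, 0.45), "stroke": (0.25, 0.45), "ckd": (0.35, 0.55),
                       "cancer": (0.10, 0.30), "dm1": (0.25, 0.45)},
    }
    m4_6 = {
        "ceasefire": {"ihd": (0.60, 0.80), "stroke": (0.60, 0.80), "ckd": (0.65, 0.85),
                      "cancer": (0.25, 0.45), "dm1": (0.70, 0.90)},
        "status_quo": m1_3["status_quo"],
        "escalation": {"ihd": (0.20, 0.40), "stroke": (0.20, 0.40), "ckd": (0.30, 0.50),
                       "cancer": (0.10, 0.30), "dm1": (0.20, 0.40)},
    }
    for scen in SCENARIOS:
        for d in diseases:
            coverage[(d, "to_date", scen)] = to_date[d]
            coverage[(d, "proj_m1_3", scen)] = m1_3[scen][d]
            coverage[(d, "proj_m4_6", scen)] = m4_6[scen][d]

    grid = TimeGrid()  # Jan 2000 origin, war onset month 285
    pop_shares = (0.30, 0.21, 0.17, 0.12, 0.08, 0.05, 0.037, 0.022, 0.011)
    population = PopulationTable(
        {s: round(2.2e6 * p) for s, p in zip(AGE_STRATA, pop_shares)}
    )
    baseline_years = tuple(range(2017, 2023))
    return diseases, coverage, grid, population, baseline_years, 1000


def _small_catalogue():
    """Three diseases (one per model kind) on a short grid, for fast tests."""
    diseases = {
        "ihd": dict(
            kind="cvd_acute",
            acute=AcuteRisk(treated=0.05, untreated=0.30),
            hazards={
                "treated": (_hm("lognormal", {"mu": float(np.log(60.0)), "sigma": 1.2}, "treated"),),
                "untreated": (_hm("lognormal", {"mu": float(np.log(12.0)), "sigma": 1.2}, "untreated"),),
            },
            incidence=100.0,
            monthly_baseline=90.0,
            age_shares=(0.001, 0.002, 0.007, 0.02, 0.06, 0.13, 0.20, 0.26, 0.32),
        ),
        "ckd": dict(
            kind="chronic",
            hazards={
                "treated": (_hm("exponential", {"rate": 0.004}, "treated"),),
                "untreated": (
                    _hm("exponential", {"rate": 0.20}, "untreated", "lower"),
                    _hm("exponential", {"rate": 0.10}, "untreated", "upper"),
                ),
            },
            incidence=10.0,
            monthly_baseline=12.0,
            age_shares=(0.01, 0.02, 0.04, 0.06, 0.10, 0.17, 0.22, 0.21, 0.17),
        ),
        "dm1": dict(
            kind="prevalent_pool",
            hazards={
                "treated": (_hm("exponential", {"rate": 0.0003}, "treated"),),
                "untreated": (_hm("exponential", {"rate": 0.05}, "untreated"),),
            },
            pool=800.0,
            age_shares=(0.15, 0.25, 0.20, 0.15, 0.10, 0.07, 0.05, 0.02, 0.01),
        ),
    }
    coverage = {}
    to_date = {"ihd": (0.30, 0.50), "ckd": (0.40, 0.60), "dm1": (0.40, 0.60)}
    proj = {
        "ceasefire": {"ihd": (0.55, 0.75), "ckd": (0.60, 0.80), "dm1": (0.65, 0.85)},
        "status_quo": {"ihd": (0.35, 0.55), "ckd": (0.45, 0.65), "dm1": (0.40, 0.60)},
        "escalation": {"ihd": (0.25, 0.45), "ckd": (0.35, 0.55), "dm1": (0.25, 0.45)},
    }
    for d in diseases:
        coverage[(d, "baseline", "baseline")] = (0.90, 1.00)
        for scen in SCENARIOS:
            coverage[(d, "to_date", scen)] = to_date[d]
            coverage[(d, "proj_m1_3", scen)] = proj[scen][d]
            coverage[(d, "proj_m4_6", scen)] = proj[scen][d]

    grid = TimeGrid(war_start=45, origin_year=2020)
    pop_shares = (0.30, 0.21, 0.17, 0.12, 0.08, 0.05, 0.037, 0.022, 0.011)
    population = PopulationTable(
        {s: round(2.2e6 * p) for s, p in zip(AGE_STRATA, pop_shares)}
    )
    baseline_years = (2020, 2021, 2022)
    return diseases, coverage, grid, population, baseline_years, 50


#: true annual log-trend slope of baseline deaths (per year)
TRUE_SLOPE = 0.02


def generate_inputs(seed: int, profile: str = "small") -> tuple[ScenarioBundle, GroundTruth]:
    """Generate a validated scenario bundle plus its ground truth.

    ``profile="paper_like"`` emits five disease groups on the full
    2000-2024 monthly grid with 1000 runs; ``"small"`` emits three
    diseases (one per model kind) on a short grid for fast tests.
    Deterministic given ``seed``.
    """
    if profile == "paper_like":
        catalogue, coverage_ranges, grid, population, years, n_runs = _paper_like_catalogue()
    elif profile == "small":
        catalogue, coverage_ranges, grid, population, years, n_runs = _small_catalogue()
    else:
        raise ValueError(f"unknown profile {profile!r}")

    rng = np.random.default_rng(seed)
    coverage = CoverageSchedule(coverage_ranges)

    diseases: list[DiseaseSpec] = []
    obs_by_disease = {}
    truth = GroundTruth(
        hazards={}, incidence={}, trends={}, pool_sizes={}, coverage=coverage
    )
    final_year = years[-1]
    for did, cfg in catalogue.items():
        age_dist = AgeDistribution(did, dict(zip(AGE_STRATA, cfg["age_shares"])))
        series = None
        if cfg["kind"] != "prevalent_pool":
            annual_final = 12.0 * cfg["monthly_baseline"]
            log_rate0 = float(np.log(annual_final) - TRUE_SLOPE * (final_year - years[0]))
            rates = np.exp(log_rate0 + TRUE_SLOPE * (np.array(years) - years[0]))
            counts = rng.poisson(rates).astype(float)
            counts = np.maximum(counts, 1.0)  # keep the GLM well defined
            series = BaselineSeries(disease=did, years=years, deaths=tuple(counts))
            truth.trends[did] = (years[0], log_rate0, TRUE_SLOPE)
            truth.incidence[did] = cfg["incidence"]
        else:
            truth.pool_sizes[did] = cfg["pool"]
        truth.hazards[did] = cfg["hazards"]

        diseases.append(
            DiseaseSpec(
                id=did,
                kind=cfg["kind"],
                hazards=cfg["hazards"],
                age_dist=age_dist,
                baseline_series=series,
                acute=cfg.get("acute"),
                mean_incidence=cfg.get("incidence"),
                prevalent_pool_size=cfg.get("pool"),
            )
        )
        # digitised-style survival points from the true curves
        times = [6.0, 12.0, 24.0, 60.0, 120.0]
        obs = []
        for arm_models in cfg["hazards"].values():
            for m in arm_models:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    obs.extend(
                        generate_survival_observations(m, times, 200, rng, source=f"{did}:{m.bound}")
                    )
        obs_by_disease[did] = obs

    bundle = ScenarioBundle(
        diseases=diseases,
        coverage=coverage,
        population=population,
        grid=grid,
        n_runs=n_runs,
        seed=seed,
        survival_observations=obs_by_disease,
    )
    _attach_expectations(bundle, truth)
    return bundle, truth


# ---------------------------------------------------------------------------
# Analytic expectation oracle (onset-cohort accumulation)
# ---------------------------------------------------------------------------

def _expected_cohort_deaths(
    incident: np.ndarray,
    coverage: np.ndarray,
    q_t: np.ndarray,
    q_u: np.ndarray,
    tau_max: int,
    acute: tuple[float, float] | None = None,
) -> np.ndarray:
    """Expected monthly deaths summed over onset cohorts.

    For each onset month the cohort's survival is accumulated forward as a
    product of one-month survival probabilities under the coverage-mixed
    death probability; cohorts are dropped once tau exceeds tau_max.
    """
    n_months = len(coverage)
    deaths = np.zeros(n_months)
    for s in range(n_months):
        n0 = float(incident[s])
        if n0 == 0.0:
            continue
        if acute is not None:
            p_acute = coverage[s] * acute[0] + (1.0 - coverage[s]) * acute[1]
            deaths[s] += n0 * p_acute
            n0 *= 1.0 - p_acute
        horizon = min(tau_max + 1, n_months - s)
        c = coverage[s:s + horizon]
        q = c * q_t[:horizon] + (1.0 - c) * q_u[:horizon]
        alive_before = np.concatenate(([1.0], np.cumprod(1.0 - q)[:-1]))
        deaths[s:s + horizon] += n0 * alive_before * q
    return deaths


def _midpoint_coverage(
    bundle: ScenarioBundle, disease_id: str, scenario: str | None
) -> np.ndarray:
    """Coverage path at range midpoints; None = counterfactual (baseline)."""
    grid = bundle.grid
    lo, hi = bundle.coverage.range_for(disease_id, "baseline")
    path = np.full(grid.n_months, 0.5 * (lo + hi))
    if scenario is not None:
        for period in WAR_PERIODS:
            plo, phi = bundle.coverage.range_for(disease_id, period, scenario)
            path[grid.period_slice(period)] = 0.5 * (plo + phi)
    return path


def _attach_expectations(bundle: ScenarioBundle, truth: GroundTruth) -> None:
    grid = bundle.grid
    for d in bundle.diseases:
        q_t = arm_death_prob_grid(d.hazards["treated"], grid.tau_max, w=0.5,
                                  phi_cfr=d.phi_cfr)
        q_u = arm_death_prob_grid(d.hazards["untreated"], grid.tau_max, w=0.5,
                                  phi_cfr=d.phi_cfr)
        acute = None
        if d.kind == "cvd_acute":
            acute = (d.acute.treated * d.phi_cfr, d.acute.untreated * d.phi_cfr)

        base_path = _midpoint_coverage(bundle, d.id, None)
        if d.kind == "prevalent_pool":
            incident = np.zeros(grid.n_months)
            incident[grid.war_start] = d.prevalent_pool_size
            k = None
        else:
            # calibrate exactly as the pipeline does, but through this oracle
            trend = fit_baseline_trend(d.baseline_series)
            target = forecast_monthly_baseline(trend, grid, grid.n_months)
            raw = np.full(grid.n_months, d.mean_incidence * d.phi_incidence)
            d_raw = _expected_cohort_deaths(raw, base_path, q_t, q_u, grid.tau_max, acute)
            window = slice(grid.war_start - 12, grid.war_start)
            k = float(np.mean(target[window]) / np.mean(d_raw[window]))
            truth.calibration_k[d.id] = k
            incident = raw * k

        counter = _expected_cohort_deaths(incident, base_path, q_t, q_u, grid.tau_max, acute)
        for scenario in SCENARIOS:
            crisis_path = _midpoint_coverage(bundle, d.id, scenario)
            crisis = _expected_cohort_deaths(
                incident, crisis_path, q_t, q_u, grid.tau_max, acute
            )
            truth.expected_monthly.setdefault(scenario, {})[d.id] = {
                "crisis": crisis, "counterfactual": counter,
            }
            excess = crisis - counter
            per_period = {
                p: float(excess[grid.period_slice(p)].sum()) for p in WAR_PERIODS
            }
            per_period["total"] = float(excess[grid.war_start:].sum())
            truth.expected_excess.setdefault(scenario, {})[d.id] = per_period
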