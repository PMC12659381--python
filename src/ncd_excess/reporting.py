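"""Scenario orchestration and excess-death summaries.

For each Monte-Carlo run a crisis-exposed cohort and a counterfactual
cohort are tracked side by side with common random numbers: both arms
share the incident-case draws, the survival-bound mixing weight, the
per-period coverage uniforms (mapped onto each arm's own coverage range)
and the per-month death-draw streams.  Per-run excess deaths are the
month-by-month difference between arms, so setting the crisis coverage
ranges equal to the baseline ranges yields exactly zero excess.

Summaries report the mean and the empirical central 95% interval
(2.5th/97.5th percentiles across runs) of excess deaths by disease,
scenario, sub-period and age stratum.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .baseline import (
    AgeDistribution,
    fit_baseline_trend,
    forecast_monthly_baseline,
)
from .cohort import (
    SCENARIOS,
    WAR_PERIODS,
    ConfigError,
    DiseaseSpec,
    RunLedger,
    _ledger_loop,
    arm_death_prob_grid,
    calibrate_incidence,
)
from .config_io import AGE_STRATA, ScenarioBundle, round_half_up

__all__ = [
    "ExcessSummary",
    "baseline_forecasts",
    "calibrate_bundle",
    "run_projection",
    "summarise_runs",
    "percentile_interval",
    "age_share",
]

# sub-streams per (scenario, disease): coverage uniforms, bound weight,
# incidence draws, death draws
_S_COV, _S_W, _S_INC, _S_DEATH = 0, 1, 2, 3


@dataclass
class ExcessSummary:
    """Mean and 95% percentile interval of excess deaths, plus trajectories."""

    scenario: str
    table: pd.DataFrame  # disease, scenario, sub_period, stratum, stats
    monthly: pd.DataFrame  # month, scenario, mean_crisis, mean_counterfactual, mean_excess
    n_runs: int


def baseline_forecasts(bundle: ScenarioBundle) -> dict[str, np.ndarray]:
    """Monthly counterfactual (GLM-forecast) deaths per disease over the grid.

    Prevalent-pool diseases (type-1 diabetes) have no baseline series:
    their counterfactual mortality is taken as zero.
    """
    grid = bundle.grid
    out: dict[str, np.ndarray] = {}
    for d in bundle.diseases:
        if d.kind == "prevalent_pool" or d.baseline_series is None:
            out[d.id] = np.zeros(grid.n_months)
            continue
        trend = fit_baseline_trend(d.baseline_series)
        out[d.id] = forecast_monthly_baseline(trend, grid, grid.n_months)
    return out


def calibrate_bundle(bundle: ScenarioBundle) -> dict[str, float]:
    """Calibrate every incident-cohort disease against its baseline forecast."""
    forecasts = baseline_forecasts(bundle)
    ks: dict[str, float] = {}
    for d in bundle.diseases:
        if d.kind == "prevalent_pool":
            continue
        base_range = bundle.coverage.range_for(d.id, "baseline")
        ks[d.id] = calibrate_incidence(d, forecasts[d.id], base_range, bundle.grid)
    return ks


def _seed_rng(bundle_seed: int, scen_idx: int, disease_idx: int, stream: int):
    ss = np.random.SeedSequence(
        entropy=(int(bundle_seed), scen_idx, disease_idx, stream)
    )
    return np.random.Generator(np.random.PCG64(ss))


def _coverage_paths(
    bundle: ScenarioBundle, disease_id: str, scenario: str, u: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Crisis and counterfactual coverage paths from shared period uniforms.

    ``u`` has one column per period (baseline, to date, months 1-3,
    months 4-6); both arms map the same uniform onto their own range, so
    identical ranges give identical paths.
    """
    grid = bundle.grid
    n_runs = u.shape[0]
    c_crisis = np.empty((n_runs, grid.n_months))
    c_base = np.empty((n_runs, grid.n_months))

    lo, hi = bundle.coverage.range_for(disease_id, "baseline")
    burn = grid.period_slice("baseline")
    base_burn = lo + u[:, 0] * (hi - lo)
    c_crisis[:, burn] = base_burn[:, None]
    c_base[:, burn] = base_burn[:, None]

    for j, period in enumerate(WAR_PERIODS, start=1):
        sl = grid.period_slice(period)
        c_base[:, sl] = (lo + u[:, j] * (hi - lo))[:, None]
        plo, phi = bundle.coverage.range_for(disease_id, period, scenario)
        c_crisis[:, sl] = (plo + u[:, j] * (phi - plo))[:, None]
    return c_crisis, c_base


def run_projection(
    bundle: ScenarioBundle,
    scenario: str,
    mode: str = "stochastic",
    n_runs: int | None = None,
) -> list[RunLedger]:
    """Run paired crisis/counterfactual cohorts for one scenario.

    Returns one :class:`RunLedger` per Monte-Carlo run (a single ledger in
    expectation mode).  Triggers incidence calibration if not yet done.
    """
    if scenario not in SCENARIOS:
        raise ConfigError(
            f"unknown scenario {scenario!r}; valid scenarios: {', '.join(SCENARIOS)}"
        )
    grid = bundle.grid
    scen_idx = SCENARIOS.index(scenario)
    expectation = mode == "expectation"
    if mode not in ("stochastic", "expectation"):
        raise ValueError(f"mode must be stochastic|expectation, got {mode!r}")
    n_runs = 1 if expectation else (n_runs or bundle.n_runs)

    if any(
        d.calibration_k is None and d.kind != "prevalent_pool" for d in bundle.diseases
    ):
        calibrate_bundle(bundle)

    ws = grid.war_start
    n_periods = 1 + len(WAR_PERIODS)
    crisis_all: dict[str, np.ndarray] = {}
    base_all: dict[str, np.ndarray] = {}
    cov_record: dict[str, np.ndarray] = {}
    w_record: dict[str, np.ndarray] = {}

    for i, d in enumerate(bundle.diseases):
        if expectation:
            u = np.full((1, n_periods), 0.5)
            w = np.full(1, 0.5)
        else:
            u = _seed_rng(bundle.seed, scen_idx, i, _S_COV).random((n_runs, n_periods))
            w = _seed_rng(bundle.seed, scen_idx, i, _S_W).random(n_runs)
        c_crisis, c_base = _coverage_paths(bundle, d.id, scenario, u)

        has_pair = any(len(models) == 2 for models in d.hazards.values())
        w_mix = w if has_pair else np.full(n_runs, 0.5)
        q_t = arm_death_prob_grid(d.hazards["treated"], grid.tau_max,
                                  w=w_mix if len(d.hazards["treated"]) == 2 else 0.5,
                                  phi_cfr=d.phi_cfr)
        q_u = arm_death_prob_grid(d.hazards["untreated"], grid.tau_max,
                                  w=w_mix if len(d.hazards["untreated"]) == 2 else 0.5,
                                  phi_cfr=d.phi_cfr)
        q_t = np.broadcast_to(np.atleast_2d(q_t), (n_runs, grid.tau_max + 1))
        q_u = np.broadcast_to(np.atleast_2d(q_u), (n_runs, grid.tau_max + 1))

        death_key = (int(bundle.seed), scen_idx, i, _S_DEATH)
        acute = None
        if d.kind == "cvd_acute":
            mu = np.clip(
                np.array([d.acute.treated, d.acute.untreated]) * d.phi_cfr, 0.0, 1.0
            )
            acute = (float(mu[0]), float(mu[1]))

        if d.kind == "prevalent_pool":
            pool = int(round(d.prevalent_pool_size))
            incident = np.zeros((n_runs, grid.n_months - ws),
                                dtype=np.int64 if not expectation else float)
            incident[:, 0] = pool if not expectation else d.prevalent_pool_size
            # pool is exposed from war onset; nothing happens before
            deaths_c, _ = _ledger_loop(
                incident, c_crisis[:, ws:], q_t, q_u, grid.tau_max, mode,
                death_key=None if expectation else death_key, month_offset=ws,
            )
            deaths_b, _ = _ledger_loop(
                incident, c_base[:, ws:], q_t, q_u, grid.tau_max, mode,
                death_key=None if expectation else death_key, month_offset=ws,
            )
            pad = np.zeros((n_runs, ws))
            crisis_all[d.id] = np.hstack([pad, deaths_c])
            base_all[d.id] = np.hstack([pad, deaths_b])
        else:
            mean_inc = (d.calibration_k or 0.0) * d.mean_incidence * d.phi_incidence
            if expectation:
                incident = np.full((1, grid.n_months), mean_inc)
            else:
                rng_inc = _seed_rng(bundle.seed, scen_idx, i, _S_INC)
                incident = rng_inc.poisson(mean_inc, size=(n_runs, grid.n_months))
            # the pre-war segment is identical in both arms: simulate once
            burn_deaths, alive_ws = _ledger_loop(
                incident[:, :ws], c_base[:, :ws], q_t, q_u, grid.tau_max, mode,
                acute=acute, death_key=None if expectation else death_key,
            )
            deaths_c, _ = _ledger_loop(
                incident[:, ws:], c_crisis[:, ws:], q_t, q_u, grid.tau_max, mode,
                acute=acute, death_key=None if expectation else death_key,
                start_alive=alive_ws, month_offset=ws,
            )
            deaths_b, _ = _ledger_loop(
                incident[:, ws:], c_base[:, ws:], q_t, q_u, grid.tau_max, mode,
                acute=acute, death_key=None if expectation else death_key,
                start_alive=alive_ws, month_offset=ws,
            )
            crisis_all[d.id] = np.hstack([burn_deaths, deaths_c])
            base_all[d.id] = np.hstack([burn_deaths, deaths_b])

        cov_record[d.id] = np.stack(
            [
                np.stack([c_crisis[:, grid.period_slice(p)][:, 0],
                          c_base[:, grid.period_slice(p)][:, 0]], axis=1)
                for p in WAR_PERIODS
            ],
            axis=1,
        )  # (runs, war periods, 2)
        w_record[d.id] = w_mix

    ledgers = []
    for r in range(n_runs):
        ledgers.append(
            RunLedger(
                run=r,
                scenario=scenario,
                crisis={did: crisis_all[did][r] for did in crisis_all},
                counterfactual={did: base_all[did][r] for did in base_all},
                coverage={
                    (did, p): (
                        float(cov_record[did][r, j, 0]),
                        float(cov_record[did][r, j, 1]),
                    )
                    for did in cov_record
                    for j, p in enumerate(WAR_PERIODS)
                },
                bound_weight={did: float(w_record[did][r]) for did in w_record},
            )
        )
    return ledgers


def percentile_interval(x: np.ndarray) -> tuple[float, float]:
    """Empirical central 95% interval: 2.5th and 97.5th percentiles."""
    lo, hi = np.percentile(np.asarray(x, dtype=float), [2.5, 97.5])
    return float(lo), float(hi)


def _ordered_strata(age_dists: Mapping[str, AgeDistribution]) -> list[str]:
    seen: list[str] = []
    for dist in age_dists.values():
        for s in dist.shares:
            if s not in seen:
                seen.append(s)
    canonical = [s for s in AGE_STRATA if s in seen]
    extras = [s for s in seen if s not in AGE_STRATA]
    return canonical + extras


def summarise_runs(
    ledgers: Sequence[RunLedger],
    grid,
    age_dists: Mapping[str, AgeDistribution],
) -> ExcessSummary:
    """Aggregate run ledgers into the reporting tables.

    Age rows allocate each run's per-disease excess by the disease's age
    distribution before taking percentiles, so the interval reflects
    run-to-run variation, not rounding of a mean.
    """
    if not ledgers:
        raise ValueError("at least one run ledger is required")
    scenario = ledgers[0].scenario
    diseases = list(ledgers[0].crisis)
    n_runs = len(ledgers)
    n_months = len(ledgers[0].crisis[diseases[0]])

    crisis = {d: np.stack([led.crisis[d] for led in ledgers]) for d in diseases}
    base = {d: np.stack([led.counterfactual[d] for led in ledgers]) for d in diseases}

    sub_periods = list(WAR_PERIODS) + ["total"]

    def period_sum(mat: np.ndarray, period: str) -> np.ndarray:
        if period == "total":
            sl = slice(grid.war_start, grid.n_months)
        else:
            sl = grid.period_slice(period)
        return mat[:, sl].sum(axis=1)

    rows = []
    excess_by_dp: dict[tuple[str, str], np.ndarray] = {}
    for d in diseases:
        for p in sub_periods:
            cr = period_sum(crisis[d], p)
            ba = period_sum(base[d], p)
            ex = cr - ba
            excess_by_dp[(d, p)] = ex
            lo, hi = percentile_interval(ex)
            rows.append(
                {"disease": d, "scenario": scenario, "sub_period": p, "stratum": "all",
                 "mean": float(ex.mean()), "pi_lo": lo, "pi_hi": hi,
                 "mean_crisis": float(cr.mean()), "mean_counterfactual": float(ba.mean())}
            )
    for p in sub_periods:
        cr = sum(period_sum(crisis[d], p) for d in diseases)
        ba = sum(period_sum(base[d], p) for d in diseases)
        ex = cr - ba
        lo, hi = percentile_interval(ex)
        rows.append(
            {"disease": "all", "scenario": scenario, "sub_period": p, "stratum": "all",
             "mean": float(ex.mean()), "pi_lo": lo, "pi_hi": hi,
             "mean_crisis": float(cr.mean()), "mean_counterfactual": float(ba.mean())}
        )

    strata = _ordered_strata(age_dists)
    for p in sub_periods:
        per_stratum = {s: np.zeros(n_runs) for s in strata}
        for d in diseases:
            shares = age_dists[d].shares
            ex = excess_by_dp[(d, p)]
            for s in strata:
                per_stratum[s] += ex * shares.get(s, 0.0)
        for s in strata:
            lo, hi = percentile_interval(per_stratum[s])
            rows.append(
                {"disease": "all", "scenario": scenario, "sub_period": p, "stratum": s,
                 "mean": float(per_stratum[s].mean()), "pi_lo": lo, "pi_hi": hi,
                 "mean_crisis": np.nan, "mean_counterfactual": np.nan}
            )

    table = pd.DataFrame(rows)

    total_crisis = sum(crisis[d] for d in diseases)
    total_base = sum(base[d] for d in diseases)
    monthly = pd.DataFrame(
        {
            "month": np.arange(n_months),
            "scenario": scenario,
            "mean_crisis": total_crisis.mean(axis=0),
            "mean_counterfactual": total_base.mean(axis=0),
            "mean_excess": (total_crisis - total_base).mean(axis=0),
        }
    )
    return ExcessSummary(scenario=scenario, table=table, monthly=monthly, n_runs=n_runs)


def age_share(
    summary: "ExcessSummary | Mapping[str, float]",
    threshold_stratum: str = "50-59",
    sub_period: str = "total",
) -> int:
    """Share (percent, rounded to integer) of excess deaths at or above an age.

    Accepts either an :class:`ExcessSummary` (its age rows for the chosen
    sub-period) or a plain mapping of stratum -> excess deaths, e.g. a
    published point-estimate table.
    """
    if isinstance(summary, Mapping):
        values = {str(k): float(v) for k, v in summary.items()}
    else:
        age_rows = summary.table[
            (summary.table.disease == "all")
            & (summary.table.stratum != "all")
            & (summary.table.sub_period == sub_period)
        ]
        if not len(age_rows):
            raise ValueError("summary contains no age-stratified rows")
        values = dict(zip(age_rows.stratum, age_rows["mean"]))

    for s in values:
        if s not in AGE_STRATA:
            raise ValueError(f"unknown age stratum {s!r}")
    if threshold_stratum not in values:
        raise ValueError(f"threshold stratum {threshold_stratum!r} missing from data")
    order = {s: i for i, s in enumerate(AGE_STRATA)}
    cut = order[threshold_stratum]
    above = sum(v for s, v in values.items() if order[s] >= cut)
    total = sum(values.values())
    if total == 0:
        raise ValueError("total excess is zero; age share undefined")
    return round_half_up(100.0 * above / total)
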