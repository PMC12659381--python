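"""Cohort engine: sampling, ledger dynamics, acute branch, pool, calibration."""

import numpy as np
import pytest

from ncd_excess import (
    AcuteRisk,
    AgeDistribution,
    CoverageSchedule,
    DiseaseSpec,
    HazardModel,
    TimeGrid,
    calibrate_incidence,
    discrete_death_prob,
    sample_coverage,
    sample_hazard,
    simulate_chronic,
    simulate_cvd,
    simulate_prevalent_pool,
)
from ncd_excess.cohort import arm_death_prob_grid

UNIFORM_AGES = AgeDistribution("d", {f"{10*i}-{10*i+9}" if i < 8 else "80+": 1 / 9 for i in range(9)})


def make_chronic(rate_t=0.004, rate_u=0.10, incidence=50.0, k=1.0, disease="d"):
    return DiseaseSpec(
        id=disease,
        kind="chronic",
        hazards={
            "treated": (HazardModel("exponential", {"rate": rate_t}, arm="treated"),),
            "untreated": (HazardModel("exponential", {"rate": rate_u}, arm="untreated"),),
        },
        age_dist=UNIFORM_AGES,
        mean_incidence=incidence,
        calibration_k=k,
    )


def q_grids(spec, grid):
    q_t = arm_death_prob_grid(spec.hazards["treated"], grid.tau_max)
    q_u = arm_death_prob_grid(spec.hazards["untreated"], grid.tau_max)
    return q_t, q_u


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def test_sample_coverage_degenerate_support_and_mean():
    sched = CoverageSchedule({("d", "to_date", "escalation"): (0.90, 1.00),
                              ("d", "baseline", "baseline"): (0.95, 0.95)})
    rng = np.random.default_rng(0)
    assert sample_coverage(sched, "d", "baseline", "baseline", rng) == 0.95
    draws = np.array(
        [sample_coverage(sched, "d", "to_date", "escalation", rng) for _ in range(10_000)]
    )
    assert draws.min() >= 0.90 and draws.max() <= 1.00
    # Uniform(0.9, 1.0): mean 0.95, sd 0.1/sqrt(12); 3-sigma band on the mean
    assert abs(draws.mean() - 0.95) < 3 * 0.1 / np.sqrt(12 * 10_000)


def test_sample_coverage_missing_entry_errors():
    from ncd_excess import ConfigError

    sched = CoverageSchedule({})
    with pytest.raises(ConfigError, match="no coverage range"):
        sample_coverage(sched, "d", "to_date", "escalation", np.random.default_rng(0))


def test_sample_hazard_single_model_and_bound_mixture():
    single = (HazardModel("exponential", {"rate": 0.02}),)
    q = sample_hazard(single, np.random.default_rng(0))
    tau = np.arange(5.0)
    assert np.allclose(q(tau), discrete_death_prob(single[0], tau))
    assert q.w is None

    pair = (
        HazardModel("exponential", {"rate": 0.20}, bound="lower"),
        HazardModel("exponential", {"rate": 0.10}, bound="upper"),
    )
    # w = 0 endpoint reproduces the upper-bound curve exactly
    q0 = arm_death_prob_grid(pair, 10, w=0.0)
    assert np.allclose(q0, discrete_death_prob(pair[1], np.arange(11.0)))
    # mean over draws converges to the midpoint (q linear in w)
    rng = np.random.default_rng(1)
    draws = np.array([sample_hazard(pair, rng)(12.0) for _ in range(10_000)])
    q_lo = discrete_death_prob(pair[0], 12.0)
    q_up = discrete_death_prob(pair[1], 12.0)
    half_width = (q_lo - q_up) / 2
    mc_se = abs(half_width) / np.sqrt(3 * 10_000)
    assert abs(draws.mean() - (q_lo + q_up) / 2) < 3 * mc_se


# ---------------------------------------------------------------------------
# Chronic ledger
# ---------------------------------------------------------------------------

def test_full_coverage_zero_treated_hazard_kills_nobody():
    grid = TimeGrid(war_start=24, origin_year=2020)
    spec = make_chronic()
    coverage = np.ones(grid.n_months)
    q_zero = np.zeros(grid.tau_max + 1)
    _, q_u = q_grids(spec, grid)
    deaths = simulate_chronic(spec, coverage, q_zero, q_u, grid, mode="expectation")
    assert np.all(deaths == 0.0)


def test_renewal_equilibrium_matches_incidence():
    """Untreated-only exponential cohort: at equilibrium deaths = incidence.

    Every case eventually dies, so once the ledger has burnt in for many
    mean lifetimes the monthly deaths equal the constant inflow.
    """
    lam = 0.05
    grid = TimeGrid(war_start=300, origin_year=2000, tau_max=600)
    spec = make_chronic(rate_u=lam, incidence=100.0)
    coverage = np.zeros(grid.n_months)
    q_t, q_u = q_grids(spec, grid)
    deaths = simulate_chronic(spec, coverage, q_t, q_u, grid, mode="expectation")
    assert deaths[-1] == pytest.approx(100.0, rel=1e-3)


def test_stochastic_mean_matches_expectation_mode():
    grid = TimeGrid(war_start=50, origin_year=2020, tau_max=50)
    spec = make_chronic(rate_u=0.08, incidence=30.0)
    coverage = np.full(grid.n_months, 0.6)
    q_t, q_u = q_grids(spec, grid)
    expect = simulate_chronic(spec, coverage, q_t, q_u, grid, mode="expectation")

    n_runs = 200
    rng = np.random.default_rng(42)
    cov2 = np.broadcast_to(coverage, (n_runs, grid.n_months))
    stoch = simulate_chronic(spec, cov2, q_t, q_u, grid, rng=rng, mode="stochastic")
    se = stoch.std(axis=0, ddof=1) / np.sqrt(n_runs)
    diff = np.abs(stoch.mean(axis=0) - expect)
    assert np.all(diff <= 3 * se + 1e-9)


def test_q_outside_unit_interval_rejected():
    grid = TimeGrid(war_start=5, origin_year=2020)
    spec = make_chronic()
    coverage = np.ones(grid.n_months)
    bad = np.full(grid.tau_max + 1, 1.5)
    with pytest.raises(ValueError, match="outside"):
        simulate_chronic(spec, coverage, bad, bad, grid, mode="expectation")


def test_conservation_and_coverage_monotonicity():
    grid = TimeGrid(war_start=40, origin_year=2020)
    spec = make_chronic(rate_t=0.01, rate_u=0.15, incidence=20.0)
    q_t, q_u = q_grids(spec, grid)
    high = np.full(grid.n_months, 0.9)
    low = np.full(grid.n_months, 0.4)
    d_high = simulate_chronic(spec, high, q_t, q_u, grid, mode="expectation")
    d_low = simulate_chronic(spec, low, q_t, q_u, grid, mode="expectation")
    # lower coverage can only increase deaths when q_U >= q_T
    assert np.all(d_low >= d_high - 1e-12)
    # cumulative deaths never exceed cumulative incidence
    assert np.all(np.cumsum(d_low) <= 20.0 * np.arange(1, grid.n_months + 1) + 1e-9)


def test_aggregate_equals_sum_of_age_stratified_runs():
    """Expectation ledger is linear in incidence, so simulating the aggregate
    cohort and allocating by age equals simulating each stratum separately."""
    grid = TimeGrid(war_start=30, origin_year=2020)
    spec = make_chronic(incidence=45.0)
    coverage = np.full(grid.n_months, 0.7)
    q_t, q_u = q_grids(spec, grid)
    total = simulate_chronic(spec, coverage, q_t, q_u, grid, mode="expectation")
    shares = (0.2, 0.3, 0.5)
    parts = []
    for share in shares:
        sub = make_chronic(incidence=45.0 * share)
        parts.append(simulate_chronic(sub, coverage, q_t, q_u, grid, mode="expectation"))
    assert np.allclose(total, np.sum(parts, axis=0), atol=1e-9)
    for share, part in zip(shares, parts):
        assert np.allclose(part, total * share, atol=1e-9)


# ---------------------------------------------------------------------------
# CVD acute branch
# ---------------------------------------------------------------------------

def make_cvd(mu_t, mu_u, **kw):
    spec = make_chronic(**kw)
    return DiseaseSpec(
        id="ihd",
        kind="cvd_acute",
        hazards=spec.hazards,
        age_dist=UNIFORM_AGES,
        acute=AcuteRisk(treated=mu_t, untreated=mu_u),
        mean_incidence=spec.mean_incidence,
        calibration_k=1.0,
    )


def test_cvd_without_acute_risk_reduces_to_chronic():
    grid = TimeGrid(war_start=24, origin_year=2020)
    cvd = make_cvd(0.0, 0.0, incidence=40.0)
    chronic = make_chronic(incidence=40.0)
    coverage = np.full(grid.n_months, 0.8)
    q_t, q_u = q_grids(chronic, grid)
    d_cvd = simulate_cvd(cvd, coverage, q_t, q_u, grid, mode="expectation")
    d_chr = simulate_chronic(chronic, coverage, q_t, q_u, grid, mode="expectation")
    assert np.allclose(d_cvd, d_chr, atol=1e-12)


def test_cvd_acute_arithmetic_and_mixture():
    grid = TimeGrid(war_start=2, origin_year=2020, tau_max=5)
    q_zero = np.zeros(grid.tau_max + 1)

    # 100 incident, full coverage, mu_T = 0.2: 20 acute deaths, 80 survivors
    cvd = make_cvd(0.2, 0.5, incidence=100.0)
    deaths = simulate_cvd(cvd, np.ones(grid.n_months), q_zero, q_zero, grid,
                          mode="expectation")
    assert deaths[0] == pytest.approx(20.0)

    # c = 0.5 mixes acute risks: 0.5*0.1 + 0.5*0.3 = 0.2 of incidence
    cvd = make_cvd(0.1, 0.3, incidence=100.0)
    deaths = simulate_cvd(cvd, np.full(grid.n_months, 0.5), q_zero, q_zero, grid,
                          mode="expectation")
    assert np.allclose(deaths, 20.0)


def test_cvd_missing_acute_risk_errors():
    from ncd_excess import ConfigError

    grid = TimeGrid(war_start=5, origin_year=2020)
    spec = make_chronic()
    q_t, q_u = q_grids(spec, grid)
    with pytest.raises(ConfigError):
        simulate_cvd(spec, np.ones(grid.n_months), q_t, q_u, grid, mode="expectation")


# ---------------------------------------------------------------------------
# Prevalent pool
# ---------------------------------------------------------------------------

def make_pool(pool=1000.0, rate_u=None):
    q_u_rate = rate_u if rate_u is not None else 0.05
    return DiseaseSpec(
        id="dm1",
        kind="prevalent_pool",
        hazards={
            "treated": (HazardModel("exponential", {"rate": 1e-4}, arm="treated"),),
            "untreated": (HazardModel("exponential", {"rate": q_u_rate}, arm="untreated"),),
        },
        age_dist=UNIFORM_AGES,
        prevalent_pool_size=pool,
    )


def test_prevalent_pool_depletion_closed_form():
    grid = TimeGrid(war_start=3, origin_year=2020, tau_max=10)
    spec = make_pool(1000.0)
    coverage = np.zeros(grid.n_months)
    q_const = np.full(grid.tau_max + 1, 0.05)
    deaths = simulate_prevalent_pool(spec, coverage, q_const, q_const, grid,
                                     mode="expectation")
    assert np.all(deaths[: grid.war_start] == 0.0)
    assert deaths[grid.war_start] == pytest.approx(50.0)
    # cumulative over two months: 1000 * (1 - 0.95^2)
    assert deaths[grid.war_start:grid.war_start + 2].sum() == pytest.approx(97.5)


def test_prevalent_pool_protected_under_full_coverage():
    grid = TimeGrid(war_start=3, origin_year=2020, tau_max=10)
    spec = make_pool(500.0)
    q_zero = np.zeros(grid.tau_max + 1)
    q_u = np.full(grid.tau_max + 1, 0.3)
    deaths = simulate_prevalent_pool(spec, np.ones(grid.n_months), q_zero, q_u, grid,
                                     mode="expectation")
    assert np.all(deaths == 0.0)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def test_calibration_scales_linearly():
    """Doubling the target exactly doubles k (expected ledger linear in I)."""
    grid = TimeGrid(war_start=40, origin_year=2020)
    spec = make_chronic(rate_u=0.10, incidence=10.0, k=None)
    q_t, q_u = q_grids(spec, grid)
    base_cov = np.full(grid.n_months, 0.95)
    sim = simulate_chronic(spec, base_cov, q_t, q_u, grid, mode="expectation")

    target1 = np.full(grid.n_months, sim[grid.war_start - 12:grid.war_start].mean())
    k1 = calibrate_incidence(spec, target1, (0.90, 1.00), grid)
    assert k1 == pytest.approx(1.0, rel=1e-9)

    spec2 = make_chronic(rate_u=0.10, incidence=10.0, k=None)
    k2 = calibrate_incidence(spec2, 2.0 * target1, (0.90, 1.00), grid)
    assert k2 == pytest.approx(2.0, rel=1e-9)


def test_calibration_self_consistent_in_expectation():
    grid = TimeGrid(war_start=40, origin_year=2020)
    spec = make_chronic(rate_u=0.12, incidence=5.0, k=None)
    target = np.full(grid.n_months, 30.0)
    calibrate_incidence(spec, target, (0.90, 1.00), grid)
    q_t, q_u = q_grids(spec, grid)
    deaths = simulate_chronic(spec, np.full(grid.n_months, 0.95), q_t, q_u, grid,
                              mode="expectation")
    window = slice(grid.war_start - 12, grid.war_start)
    assert deaths[window].mean() == pytest.approx(30.0, rel=1e-9)


def test_calibration_zero_target_gives_zero_k():
    grid = TimeGrid(war_start=20, origin_year=2020)
    spec = make_chronic(k=None)
    with pytest.warns(UserWarning, match="zero baseline"):
        k = calibrate_incidence(spec, np.zeros(grid.n_months), (0.90, 1.00), grid)
    assert k == 0.0
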