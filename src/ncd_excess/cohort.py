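"""Discrete-time cohort microsimulation of NCD mortality.

Monthly incident cohorts are simulated from the grid origin (January
2000 in the full configuration) to the end of the projection period.
Each month a cohort of ``Poisson(k * I_base)`` incident cases enters at
time-since-onset tau = 0 and thereafter dies with monthly probability

    q(tau, t) = c_t * q_T(tau) + (1 - c_t) * q_U(tau),

a coverage-weighted mixture of the treated and untreated discrete death
probabilities.  Cardiovascular disease adds an immediate acute
case-fatality risk at onset, with acute survivors entering the chronic
ledger under post-acute (conditioned) hazards.  Type-1 diabetes is
modelled as a fixed prevalent pool exposed from war onset, with no
incident cases.

The calibration constant ``k`` rescales mean incidence so that the
simulated counterfactual death rate over the final pre-war year matches
the Poisson-GLM baseline forecast.  An ``expectation`` mode replaces
every random draw by its mean and is the deterministic oracle used in
testing and calibration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .baseline import AgeDistribution, BaselineSeries
from .survival import AcuteRisk, HazardModel, discrete_death_prob

__all__ = [
    "PERIODS",
    "WAR_PERIODS",
    "SCENARIOS",
    "ConfigError",
    "CalibrationError",
    "DiseaseSpec",
    "CoverageSchedule",
    "RunLedger",
    "sample_coverage",
    "sample_hazard",
    "arm_death_prob_grid",
    "simulate_chronic",
    "simulate_cvd",
    "simulate_prevalent_pool",
    "calibrate_incidence",
]

PERIODS = ("baseline", "to_date", "proj_m1_3", "proj_m4_6")
WAR_PERIODS = ("to_date", "proj_m1_3", "proj_m4_6")
SCENARIOS = ("ceasefire", "status_quo", "escalation")

KINDS = ("chronic", "cvd_acute", "prevalent_pool")


class ConfigError(ValueError):
    """A required configuration entry is missing or inconsistent."""


class CalibrationError(RuntimeError):
    """Incidence calibration cannot proceed (e.g. zero simulated deaths)."""


@dataclass
class DiseaseSpec:
    """Complete per-disease parameterisation for the cohort engine."""

    id: str
    kind: str
    hazards: Mapping[str, tuple[HazardModel, ...]]  # arm -> 1 model or (lower, upper)
    age_dist: AgeDistribution
    baseline_series: BaselineSeries | None = None
    acute: AcuteRisk | None = None
    mean_incidence: float | None = None  # I_base, cases/month (pre-calibration)
    calibration_k: float | None = None
    prevalent_pool_size: float | None = None
    phi_incidence: float = 1.0
    phi_cfr: float = 1.0
    baseline_scale: float = 1.0  # e.g. West-Bank-to-Gaza population ratio

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ConfigError(f"{self.id}: unknown disease kind {self.kind!r}")
        hz = {arm: tuple(models) for arm, models in dict(self.hazards).items()}
        for arm in ("treated", "untreated"):
            if arm not in hz or not hz[arm]:
                raise ConfigError(f"{self.id}: missing {arm} hazard model(s)")
            if len(hz[arm]) > 2:
                raise ConfigError(f"{self.id}: at most 2 bound models per arm")
        self.hazards = hz
        if self.kind in ("chronic", "cvd_acute"):
            if self.mean_incidence is None or self.mean_incidence <= 0:
                raise ConfigError(f"{self.id}: mean_incidence must be > 0")
        if self.kind == "cvd_acute" and self.acute is None:
            raise ConfigError(f"{self.id}: cvd_acute kind requires acute risks")
        if self.kind == "prevalent_pool":
            if self.prevalent_pool_size is None or self.prevalent_pool_size <= 0:
                raise ConfigError(f"{self.id}: prevalent_pool_size must be > 0")
        if self.phi_incidence <= 0 or self.phi_cfr <= 0:
            raise ConfigError(f"{self.id}: phi multipliers must be > 0")


@dataclass
class CoverageSchedule:
    """Uniform treatment-coverage ranges per disease x period x scenario."""

    ranges: Mapping[tuple[str, str, str], tuple[float, float]]

    #: pre-war essential treatment coverage assumed near-universal
    BASELINE_DEFAULT = (0.90, 1.00)

    def __post_init__(self) -> None:
        norm: dict[tuple[str, str, str], tuple[float, float]] = {}
        for (disease, period, scenario), (lo, hi) in dict(self.ranges).items():
            if period not in PERIODS:
                raise ConfigError(f"unknown period {period!r}")
            if period != "baseline" and scenario not in SCENARIOS:
                raise ConfigError(f"unknown scenario {scenario!r}")
            norm[(disease, period, scenario)] = (float(lo), float(hi))
        self.ranges = norm

    def diseases(self) -> set[str]:
        return {d for (d, _, _) in self.ranges}

    def range_for(
        self, disease: str, period: str, scenario: str = "baseline"
    ) -> tuple[float, float]:
        if period == "baseline":
            return self.ranges.get(
                (disease, "baseline", "baseline"), self.BASELINE_DEFAULT
            )
        try:
            return self.ranges[(disease, period, scenario)]
        except KeyError:
            raise ConfigError(
                f"no coverage range for disease={disease!r} period={period!r} "
                f"scenario={scenario!r}"
            ) from None


@dataclass
class RunLedger:
    """Per-run monthly deaths for the paired crisis/counterfactual cohorts."""

    run: int
    scenario: str
    crisis: Mapping[str, np.ndarray]  # disease -> deaths per month
    counterfactual: Mapping[str, np.ndarray]
    coverage: Mapping[tuple[str, str], tuple[float, float]]  # (disease, period) -> (crisis c, base c)
    bound_weight: Mapping[str, float]  # disease -> survival-bound mixing weight

    def excess(self, disease: str) -> np.ndarray:
        return self.crisis[disease] - self.counterfactual[disease]


# ---------------------------------------------------------------------------
# Sampling primitives
# ---------------------------------------------------------------------------

def sample_coverage(
    schedule: CoverageSchedule,
    disease: str,
    period: str,
    scenario: str,
    rng: np.random.Generator,
) -> float:
    """One Uniform(lo, hi) coverage draw for a disease/period/scenario."""
    lo, hi = schedule.range_for(disease, period, scenario)
    return float(rng.uniform(lo, hi)) if hi > lo else float(lo)


def _bound_pair(
    models: Sequence[HazardModel],
) -> tuple[HazardModel, HazardModel] | None:
    if len(models) == 1:
        return None
    by_bound = {m.bound: m for m in models}
    if set(by_bound) != {"lower", "upper"}:
        raise ConfigError(
            "a two-model hazard set must be labelled bound='lower' and 'upper'"
        )
    return by_bound["lower"], by_bound["upper"]


def sample_hazard(
    models: Sequence[HazardModel], rng: np.random.Generator
) -> Callable[[np.ndarray], np.ndarray]:
    """Effective monthly death-probability function for one run.

    A single model yields its own discrete death probability.  A
    lower/upper survival-bound pair is mixed as
    ``q = w * q_lower + (1 - w) * q_upper`` with one ``w ~ Uniform(0,1)``
    per run (``w = 0`` reproduces the upper-bound curve exactly).
    """
    models = tuple(models)
    if not models:
        raise ValueError("at least one hazard model is required")
    pair = _bound_pair(models)
    if pair is None:
        model = models[0]

        def q_single(tau):
            return discrete_death_prob(model, tau)

        q_single.w = None
        return q_single

    lower, upper = pair
    w = float(rng.uniform(0.0, 1.0))

    def q_mixed(tau):
        return w * discrete_death_prob(lower, tau) + (1.0 - w) * discrete_death_prob(
            upper, tau
        )

    q_mixed.w = w
    return q_mixed


def arm_death_prob_grid(
    models: Sequence[HazardModel],
    tau_max: int,
    w: float | np.ndarray = 0.5,
    phi_cfr: float = 1.0,
) -> np.ndarray:
    """Monthly death probabilities q(tau), tau = 0..tau_max, for one arm.

    ``w`` mixes a lower/upper survival-bound pair (scalar, or one weight
    per run giving a (runs, tau_max+1) array); it is ignored for a single
    model.  ``phi_cfr`` is the crisis case-fatality relative risk applied
    multiplicatively (probabilities clipped to [0, 1]).
    """
    tau = np.arange(tau_max + 1, dtype=float)
    pair = _bound_pair(tuple(models))
    if pair is None:
        q = np.asarray(discrete_death_prob(models[0], tau))
    else:
        lower, upper = pair
        q_lo = np.asarray(discrete_death_prob(lower, tau))
        q_up = np.asarray(discrete_death_prob(upper, tau))
        w_arr = np.asarray(w, dtype=float)
        if w_arr.ndim == 1:
            w_arr = w_arr[:, None]
        q = w_arr * q_lo + (1.0 - w_arr) * q_up
    return np.clip(phi_cfr * q, 0.0, 1.0)


# ---------------------------------------------------------------------------
# Core ledger recursion
# ---------------------------------------------------------------------------

def _month_rng(death_key: tuple[int, ...], month: int) -> np.random.Generator:
    # a fresh keyed generator per calendar month: both simulation arms use the
    # same key, so equal (n, p) inputs give identical draws (common random
    # numbers) while months stay mutually independent
    ss = np.random.SeedSequence(entropy=tuple(death_key) + (month,))
    return np.random.Generator(np.random.PCG64(ss))


def _as_2d(a, n_runs: int, width: int, name: str) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    if a.ndim == 1:
        a = np.broadcast_to(a, (n_runs, a.shape[0]))
    if a.shape != (n_runs, width):
        raise ValueError(f"{name} has shape {a.shape}, expected ({n_runs}, {width})")
    return a


def _ledger_loop(
    incident: np.ndarray,
    coverage: np.ndarray,
    q_t: np.ndarray,
    q_u: np.ndarray,
    tau_max: int,
    mode: str,
    acute: tuple[float, float] | None = None,
    death_key: tuple[int, ...] | None = None,
    start_alive: np.ndarray | None = None,
    month_offset: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Advance the cohort ledger month by month.

    ``incident`` (runs, months) are cases entering at tau=0; ``coverage``
    (runs, months); ``q_t``/``q_u`` (runs, tau_max+1).  Returns monthly
    deaths (runs, months) and the final alive ledger (runs, tau_max+1).
    Cohorts are retired once tau exceeds tau_max.
    """
    if mode not in ("stochastic", "expectation"):
        raise ValueError(f"mode must be stochastic|expectation, got {mode!r}")
    stochastic = mode == "stochastic"
    n_runs, n_months = incident.shape
    for name, q in (("q_T", q_t), ("q_U", q_u)):
        if np.any(q < 0) or np.any(q > 1):
            raise ValueError(f"{name} contains values outside [0, 1]")
    if stochastic and death_key is None:
        raise ValueError("stochastic mode requires a death_key")

    dtype = np.int64 if stochastic else float
    if start_alive is None:
        alive = np.zeros((n_runs, tau_max + 1), dtype=dtype)
    else:
        alive = np.array(start_alive, dtype=dtype, copy=True)
    if stochastic:
        incident = np.asarray(incident)
        if not np.issubdtype(incident.dtype, np.integer):
            raise ValueError("stochastic mode requires integer incident counts")

    deaths = np.zeros((n_runs, n_months), dtype=float)
    for t in range(n_months):
        rng = _month_rng(death_key, month_offset + t) if stochastic else None
        # age the ledger by one month (tau > tau_max retires), insert onset cohort
        alive[:, 1:] = alive[:, :-1]
        alive[:, 0] = 0
        c = coverage[:, t]
        n_new = incident[:, t]
        acute_deaths = 0.0
        if acute is not None:
            mu_t, mu_u = acute
            p_acute = c * mu_t + (1.0 - c) * mu_u
            if stochastic:
                a_d = rng.binomial(n_new, p_acute)
            else:
                a_d = n_new * p_acute
            acute_deaths = a_d
            alive[:, 0] = n_new - a_d
        else:
            alive[:, 0] = n_new
        q_mix = c[:, None] * q_t + (1.0 - c[:, None]) * q_u
        if stochastic:
            d = rng.binomial(alive, q_mix)
        else:
            d = alive * q_mix
        alive -= d
        deaths[:, t] = np.asarray(acute_deaths) + d.sum(axis=1)
    return deaths, alive


def _prep_q(q, tau_max: int, n_runs: int, name: str) -> np.ndarray:
    if callable(q):
        q = np.asarray(q(np.arange(tau_max + 1, dtype=float)), dtype=float)
    return _as_2d(q, n_runs, tau_max + 1, name)


def _derive_death_key(rng: np.random.Generator) -> tuple[int, ...]:
    return tuple(int(v) for v in rng.integers(0, 2**31 - 1, size=3))


def _effective_incidence(spec: DiseaseSpec) -> float:
    k = spec.calibration_k if spec.calibration_k is not None else 1.0
    return k * spec.mean_incidence * spec.phi_incidence


def simulate_chronic(
    spec: DiseaseSpec,
    coverage_path,
    q_T,
    q_U,
    grid,
    rng: np.random.Generator | None = None,
    mode: str = "expectation",
    incident: np.ndarray | None = None,
    death_key: tuple[int, ...] | None = None,
    n_runs: int = 1,
) -> np.ndarray:
    """Simulate monthly deaths for a chronic-disease incident-cohort model.

    ``coverage_path`` gives the per-month treated fraction; ``q_T``/``q_U``
    are per-month death probabilities by time since onset (callable on tau
    or arrays of length ``grid.tau_max + 1``).  ``incident`` overrides the
    Poisson/mean incidence draws (used by the orchestrator to share draws
    between paired arms).  Returns deaths with the leading runs axis
    squeezed away when a single run is simulated from 1-D inputs.
    """
    coverage = np.asarray(coverage_path, dtype=float)
    squeeze = coverage.ndim == 1 and (incident is None or np.asarray(incident).ndim == 1)
    n_months = coverage.shape[-1]
    if coverage.ndim == 2:
        n_runs = coverage.shape[0]
    elif incident is not None and np.asarray(incident).ndim == 2:
        n_runs = np.asarray(incident).shape[0]
    coverage = _as_2d(coverage, n_runs, n_months, "coverage_path")

    stochastic = mode == "stochastic"
    if incident is None:
        mean_inc = _effective_incidence(spec)
        if stochastic:
            if rng is None:
                raise ValueError("stochastic mode requires rng when incident not given")
            incident = rng.poisson(mean_inc, size=(n_runs, n_months))
        else:
            incident = np.full((n_runs, n_months), mean_inc)
    else:
        incident = np.asarray(incident)
        if incident.ndim == 1:
            incident = np.broadcast_to(incident, (n_runs, n_months)).copy()
    if stochastic and death_key is None:
        death_key = _derive_death_key(rng)

    q_t = _prep_q(q_T, grid.tau_max, n_runs, "q_T")
    q_u = _prep_q(q_U, grid.tau_max, n_runs, "q_U")
    deaths, _ = _ledger_loop(
        incident, coverage, q_t, q_u, grid.tau_max, mode,
        acute=None, death_key=death_key,
    )
    return deaths[0] if squeeze else deaths


def simulate_cvd(
    spec: DiseaseSpec,
    coverage_path,
    q_T,
    q_U,
    grid,
    rng: np.random.Generator | None = None,
    mode: str = "expectation",
    incident: np.ndarray | None = None,
    death_key: tuple[int, ...] | None = None,
    n_runs: int = 1,
) -> np.ndarray:
    """Chronic simulation plus an immediate acute case-fatality at onset.

    Onset-month acute deaths are ``incident * [c*mu_T + (1-c)*mu_U]``;
    acute survivors enter the chronic ledger at tau = 0 under the
    post-acute (conditioned) death probabilities ``q_T``/``q_U``.
    """
    if spec.acute is None:
        raise ConfigError(f"{spec.id}: acute case-fatality risks are required")
    coverage = np.asarray(coverage_path, dtype=float)
    squeeze = coverage.ndim == 1 and (incident is None or np.asarray(incident).ndim == 1)
    n_months = coverage.shape[-1]
    if coverage.ndim == 2:
        n_runs = coverage.shape[0]
    elif incident is not None and np.asarray(incident).ndim == 2:
        n_runs = np.asarray(incident).shape[0]
    coverage = _as_2d(coverage, n_runs, n_months, "coverage_path")

    stochastic = mode == "stochastic"
    if incident is None:
        mean_inc = _effective_incidence(spec)
        if stochastic:
            if rng is None:
                raise ValueError("stochastic mode requires rng when incident not given")
            incident = rng.poisson(mean_inc, size=(n_runs, n_months))
        else:
            incident = np.full((n_runs, n_months), mean_inc)
    else:
        incident = np.asarray(incident)
        if incident.ndim == 1:
            incident = np.broadcast_to(incident, (n_runs, n_months)).copy()
    if stochastic and death_key is None:
        death_key = _derive_death_key(rng)

    q_t = _prep_q(q_T, grid.tau_max, n_runs, "q_T")
    q_u = _prep_q(q_U, grid.tau_max, n_runs, "q_U")
    mu = np.clip(
        np.array([spec.acute.treated, spec.acute.untreated]) * spec.phi_cfr, 0.0, 1.0
    )
    deaths, _ = _ledger_loop(
        incident, coverage, q_t, q_u, grid.tau_max, mode,
        acute=(float(mu[0]), float(mu[1])), death_key=death_key,
    )
    return deaths[0] if squeeze else deaths


def simulate_prevalent_pool(
    spec: DiseaseSpec,
    coverage_path,
    q_T,
    q_U,
    grid,
    rng: np.random.Generator | None = None,
    mode: str = "expectation",
    death_key: tuple[int, ...] | None = None,
    n_runs: int = 1,
) -> np.ndarray:
    """Deplete a fixed prevalent pool from war onset; no new entrants.

    Time since onset is unknown for the pool, so tau counts from exposure
    start (war onset) -- adequate when the configured hazards are
    time-constant, as for untreated insulin-dependent diabetes.
    """
    pool = spec.prevalent_pool_size
    if pool is None or pool <= 0:
        raise ValueError(f"{spec.id}: prevalent pool size must be > 0")
    coverage = np.asarray(coverage_path, dtype=float)
    squeeze = coverage.ndim == 1
    n_months = coverage.shape[-1]
    if coverage.ndim == 2:
        n_runs = coverage.shape[0]
    coverage = _as_2d(coverage, n_runs, n_months, "coverage_path")
    if n_months <= grid.war_start:
        raise ValueError("coverage path must extend past war start")

    stochastic = mode == "stochastic"
    if stochastic and death_key is None:
        death_key = _derive_death_key(rng)
    dtype = np.int64 if stochastic else float
    incident = np.zeros((n_runs, n_months), dtype=dtype)
    incident[:, grid.war_start] = int(round(pool)) if stochastic else pool

    q_t = _prep_q(q_T, grid.tau_max, n_runs, "q_T")
    q_u = _prep_q(q_U, grid.tau_max, n_runs, "q_U")
    deaths, _ = _ledger_loop(
        incident, coverage, q_t, q_u, grid.tau_max, mode,
        acute=None, death_key=death_key,
    )
    return deaths[0] if squeeze else deaths


def calibrate_incidence(
    spec: DiseaseSpec,
    baseline_deaths: np.ndarray,
    baseline_coverage_range: tuple[float, float],
    grid,
    n_runs: int | None = None,
    rng: np.random.Generator | None = None,
    reference_months: int = 12,
) -> float:
    """Scale mean incidence so counterfactual deaths match the forecast.

    Runs the counterfactual simulation in expectation mode (deterministic,
    exploiting linearity of the expected ledger in incidence) at the raw
    ``I_base``, compares mean simulated monthly deaths over the final
    pre-war year with the baseline-forecast target, and stores
    ``k = mean(target) / mean(simulated)`` on the spec.  ``n_runs``/``rng``
    are accepted for interface symmetry but unused by the deterministic
    calibration.
    """
    if spec.kind not in ("chronic", "cvd_acute"):
        raise ConfigError(f"{spec.id}: only incident-cohort kinds are calibrated")
    baseline_deaths = np.asarray(baseline_deaths, dtype=float)
    if baseline_deaths.shape[0] < grid.war_start:
        raise ValueError("baseline_deaths must cover the full pre-war period")
    lo, hi = baseline_coverage_range
    c_mid = 0.5 * (lo + hi)
    coverage = np.full(grid.war_start, c_mid)

    q_t = arm_death_prob_grid(spec.hazards["treated"], grid.tau_max, w=0.5,
                              phi_cfr=spec.phi_cfr)
    q_u = arm_death_prob_grid(spec.hazards["untreated"], grid.tau_max, w=0.5,
                              phi_cfr=spec.phi_cfr)
    saved_k = spec.calibration_k
    spec.calibration_k = None  # simulate at raw incidence
    try:
        sim = simulate_chronic if spec.kind == "chronic" else simulate_cvd
        deaths = sim(spec, coverage, q_t, q_u, grid, mode="expectation")
    finally:
        spec.calibration_k = saved_k

    window = slice(max(grid.war_start - reference_months, 0), grid.war_start)
    target = float(np.mean(baseline_deaths[window]))
    dprime = float(np.mean(deaths[window]))
    if target == 0.0:
        warnings.warn(f"{spec.id}: zero baseline target, calibrated k = 0", stacklevel=2)
        spec.calibration_k = 0.0
        return 0.0
    if dprime <= 0.0:
        raise CalibrationError(
            f"{spec.id}: simulated counterfactual deaths are zero; cannot calibrate"
        )
    k = target / dprime
    spec.calibration_k = k
    return k
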