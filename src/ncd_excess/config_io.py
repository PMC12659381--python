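"""Configuration bundle: time grid, population, load/save, validation, outputs.

A scenario bundle is one human-readable YAML document referencing small
delimited tables (population, baseline death series, age distributions,
coverage ranges, optional survival observations).  All hazard parameters
carry an explicit time unit in the document and are normalised to
per-month units at load time; the canonical internal time unit is months
throughout the package.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .baseline import AgeDistribution, BaselineSeries
from .cohort import (
    PERIODS,
    SCENARIOS,
    ConfigError,
    CoverageSchedule,
    DiseaseSpec,
    arm_death_prob_grid,
)
from .survival import AcuteRisk, HazardModel, PARAM_NAMES, SurvivalObservation

__all__ = [
    "AGE_STRATA",
    "TimeGrid",
    "PopulationTable",
    "ScenarioBundle",
    "ConfigError",
    "hazard_params_to_monthly",
    "load_bundle",
    "save_bundle",
    "validate_bundle",
    "write_tables",
]

#: canonical age strata (years), youngest to oldest
AGE_STRATA = ("0-9", "10-19", "20-29", "30-39", "40-49",
              "50-59", "60-69", "70-79", "80+")

#: month index of 7 Oct 2023 counting from month 0 = 7 Jan 2000
WAR_START_MONTH = (2023 - 2000) * 12 + 9


@dataclass(frozen=True)
class TimeGrid:
    """Monthly time grid; months run from the 7th to the 6th of the next month.

    Month 0 starts on the 7th of January of ``origin_year``; ``war_start``
    is the month index of war onset (7 Oct 2023 = month 285 with the
    default origin).  The analysis horizon is the four-month "to date"
    sub-period followed by two three-month projection sub-periods.
    ``tau_max`` is the longest tracked time since disease onset, after
    which cohorts are retired; it defaults to the burn-in length.
    """

    war_start: int = WAR_START_MONTH
    origin_year: int = 2000
    tau_max: int | None = None
    to_date_months: int = 4
    proj1_months: int = 3
    proj2_months: int = 3
    dt: int = 1  # months; the engine is specified on a monthly step

    def __post_init__(self) -> None:
        if self.dt != 1:
            raise ValueError("dt is fixed at 1 month")
        if self.war_start <= 0:
            raise ValueError("war_start must be after the grid origin")
        if self.tau_max is None:
            object.__setattr__(self, "tau_max", self.war_start)
        if self.tau_max < 1:
            raise ValueError("tau_max must be >= 1")
        for name in ("to_date_months", "proj1_months", "proj2_months"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    @property
    def n_months(self) -> int:
        return self.war_start + self.to_date_months + self.proj1_months + self.proj2_months

    def period_slice(self, period: str) -> slice:
        """Month-index slice of a named (contiguous, non-overlapping) period."""
        b0 = self.war_start
        b1 = b0 + self.to_date_months
        b2 = b1 + self.proj1_months
        b3 = b2 + self.proj2_months
        table = {
            "baseline": slice(0, b0),
            "to_date": slice(b0, b1),
            "proj_m1_3": slice(b1, b2),
            "proj_m4_6": slice(b2, b3),
        }
        try:
            return table[period]
        except KeyError:
            raise ValueError(f"unknown period {period!r}") from None

    def year_of_month(self, month):
        """Calendar year containing the month's start day (the 7th)."""
        return self.origin_year + np.asarray(month) // 12


@dataclass(frozen=True, eq=False)
class PopulationTable:
    """Population counts by age stratum."""

    counts: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", dict(self.counts))

    @property
    def total(self) -> float:
        return float(sum(self.counts.values()))

    def __eq__(self, other) -> bool:
        return isinstance(other, PopulationTable) and dict(self.counts) == dict(other.counts)


@dataclass
class ScenarioBundle:
    """Everything one projection needs: diseases, coverage, population, grid."""

    diseases: list[DiseaseSpec]
    coverage: CoverageSchedule
    population: PopulationTable
    grid: TimeGrid
    n_runs: int = 1000
    seed: int = 0
    survival_observations: dict[str, list[SurvivalObservation]] = field(default_factory=dict)

    def disease(self, disease_id: str) -> DiseaseSpec:
        for d in self.diseases:
            if d.id == disease_id:
                return d
        raise KeyError(disease_id)


# ---------------------------------------------------------------------------
# Unit normalisation
# ---------------------------------------------------------------------------

def hazard_params_to_monthly(family: str, params: Mapping[str, float], unit: str) -> dict[str, float]:
    """Convert hazard parameters declared per-year to per-month units.

    Rates divide by 12; time-scale parameters (Weibull scale, log-logistic
    alpha) multiply by 12; the log-normal location shifts by ln 12.  The
    conversion is idempotent on per-month input.
    """
    params = dict(params)
    if unit in ("per_month", "month", "months"):
        return params
    if unit not in ("per_year", "year", "years"):
        raise ConfigError(f"unknown time unit {unit!r} (use per_month or per_year)")
    if family == "exponential":
        params["rate"] = params["rate"] / 12.0
    elif family == "weibull":
        params["scale"] = params["scale"] * 12.0
    elif family == "lognormal":
        params["mu"] = params["mu"] + math.log(12.0)
    elif family == "loglogistic":
        params["alpha"] = params["alpha"] * 12.0
    else:
        raise ConfigError(f"unknown hazard family {family!r}")
    return params


# ---------------------------------------------------------------------------
# Loading
# ---------------------------------------------------------------------------

def _require(mapping: Mapping, key: str, context: str):
    try:
        return mapping[key]
    except (KeyError, TypeError):
        raise ConfigError(f"missing required key {key!r} in {context}") from None


def _parse_hazard(entry: Mapping, disease_id: str, arm: str) -> HazardModel:
    family = _require(entry, "family", f"hazard for {disease_id}/{arm}")
    if "unit" not in entry:
        raise ConfigError(
            f"hazard for {disease_id}/{arm} ({family}) declares no time unit; "
            "state unit: per_month or per_year explicitly"
        )
    raw = _require(entry, "params", f"hazard for {disease_id}/{arm}")
    params = hazard_params_to_monthly(family, raw, entry["unit"])
    return HazardModel(
        family=family, params=params, arm=arm, bound=entry.get("bound", "point")
    )


def _parse_grid(doc: Mapping) -> TimeGrid:
    g = doc.get("grid", {})
    return TimeGrid(
        war_start=g.get("war_start", WAR_START_MONTH),
        origin_year=g.get("origin_year", 2000),
        tau_max=g.get("tau_max"),
        to_date_months=g.get("to_date_months", 4),
        proj1_months=g.get("proj1_months", 3),
        proj2_months=g.get("proj2_months", 3),
    )


def load_bundle(path: str | Path) -> ScenarioBundle:
    """Load a scenario bundle from a YAML document and its referenced tables."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config document {path} does not exist")
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    base = path.parent

    grid = _parse_grid(doc)

    pop_file = base / _require(doc, "population", str(path))
    pop_df = pd.read_csv(pop_file)
    population = PopulationTable(
        {str(r.stratum): float(r["count"]) for _, r in pop_df.iterrows()}
    )

    series_df = pd.read_csv(base / _require(doc, "baseline_series", str(path)))
    age_df = pd.read_csv(base / _require(doc, "age_distribution", str(path)))
    cov_df = pd.read_csv(base / _require(doc, "coverage", str(path)))

    ranges: dict[tuple[str, str, str], tuple[float, float]] = {}
    for _, r in cov_df.iterrows():
        ranges[(str(r.disease), str(r.period), str(r.scenario))] = (
            float(r.lo), float(r.hi)
        )
    coverage = CoverageSchedule(ranges)

    obs_by_disease: dict[str, list[SurvivalObservation]] = {}
    if "survival_observations" in doc and doc["survival_observations"]:
        obs_df = pd.read_csv(base / doc["survival_observations"])
        for _, r in obs_df.iterrows():
            tau = float(r.tau_value)
            unit = str(r.tau_unit)
            if unit in ("year", "years"):
                tau *= 12.0
            elif unit not in ("month", "months"):
                raise ConfigError(f"unknown tau_unit {unit!r} in survival observations")
            obs_by_disease.setdefault(str(r.disease), []).append(
                SurvivalObservation(
                    tau=tau,
                    surviving=float(r.surviving),
                    n_eff=None if pd.isna(r.get("n_eff")) else int(r.n_eff),
                    arm=str(r.arm),
                    source=str(r.get("source", "")),
                )
            )

    diseases: list[DiseaseSpec] = []
    for entry in _require(doc, "diseases", str(path)):
        did = _require(entry, "id", "disease entry")
        kind = _require(entry, "kind", f"disease {did}")
        hazards_doc = _require(entry, "hazards", f"disease {did}")
        hazards = {
            arm: tuple(_parse_hazard(h, did, arm) for h in models)
            for arm, models in hazards_doc.items()
        }
        acute = None
        if "acute" in entry and entry["acute"] is not None:
            acute = AcuteRisk(
                treated=float(_require(entry["acute"], "treated", f"acute risk of {did}")),
                untreated=float(_require(entry["acute"], "untreated", f"acute risk of {did}")),
            )
        sub = series_df[series_df.disease == did]
        baseline_scale = float(entry.get("baseline_scale", 1.0))
        series = None
        if len(sub):
            sub = sub.sort_values("year")
            series = BaselineSeries(
                disease=did,
                years=tuple(int(y) for y in sub.year),
                deaths=tuple(float(d) * baseline_scale for d in sub.deaths),
            )
        a_sub = age_df[age_df.disease == did]
        if not len(a_sub):
            raise ConfigError(f"missing required key: age distribution rows for {did!r}")
        age_dist = AgeDistribution(
            disease=did,
            shares={str(r.stratum): float(r.share) for _, r in a_sub.iterrows()},
        )
        diseases.append(
            DiseaseSpec(
                id=did,
                kind=kind,
                hazards=hazards,
                age_dist=age_dist,
                baseline_series=series,
                acute=acute,
                mean_incidence=entry.get("mean_incidence"),
                calibration_k=entry.get("calibration_k"),
                prevalent_pool_size=entry.get("prevalent_pool_size"),
                phi_incidence=float(entry.get("phi_incidence", 1.0)),
                phi_cfr=float(entry.get("phi_cfr", 1.0)),
                baseline_scale=baseline_scale,
            )
        )

    return ScenarioBundle(
        diseases=diseases,
        coverage=coverage,
        population=population,
        grid=grid,
        n_runs=int(doc.get("n_runs", 1000)),
        seed=int(doc.get("seed", 0)),
        survival_observations=obs_by_disease,
    )


# ---------------------------------------------------------------------------
# Saving
# ---------------------------------------------------------------------------

def save_bundle(bundle: ScenarioBundle, outdir: str | Path) -> Path:
    """Write a bundle to a directory as config.yaml plus CSV tables.

    Hazard parameters are written in per-month units, so a saved bundle
    loads back identically (unit normalisation is idempotent).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        {"stratum": list(bundle.population.counts),
         "count": list(bundle.population.counts.values())}
    ).to_csv(outdir / "population.csv", index=False)

    series_rows, age_rows = [], []
    for d in bundle.diseases:
        if d.baseline_series is not None:
            for y, n in zip(d.baseline_series.years, d.baseline_series.deaths):
                # stored series already include baseline_scale; divide so load
                # (which re-applies the scale) round-trips
                series_rows.append(
                    {"disease": d.id, "year": y, "deaths": n / d.baseline_scale}
                )
        for stratum, share in d.age_dist.shares.items():
            age_rows.append({"disease": d.id, "stratum": stratum, "share": share})
    pd.DataFrame(series_rows, columns=["disease", "year", "deaths"]).to_csv(
        outdir / "baseline_deaths.csv", index=False
    )
    pd.DataFrame(age_rows, columns=["disease", "stratum", "share"]).to_csv(
        outdir / "age_distribution.csv", index=False
    )

    cov_rows = [
        {"disease": d, "period": p, "scenario": s, "lo": lo, "hi": hi}
        for (d, p, s), (lo, hi) in bundle.coverage.ranges.items()
    ]
    pd.DataFrame(cov_rows, columns=["disease", "period", "scenario", "lo", "hi"]).to_csv(
        outdir / "coverage.csv", index=False
    )

    obs_rows = []
    for did, obs in bundle.survival_observations.items():
        for o in obs:
            obs_rows.append(
                {"disease": did, "arm": o.arm, "source": o.source, "bound": "point",
                 "tau_value": o.tau, "tau_unit": "months",
                 "surviving": o.surviving, "n_eff": o.n_eff}
            )
    if obs_rows:
        pd.DataFrame(obs_rows).to_csv(outdir / "survival_observations.csv", index=False)

    doc: dict = {
        "n_runs": bundle.n_runs,
        "seed": bundle.seed,
        "grid": {
            "war_start": bundle.grid.war_start,
            "origin_year": bundle.grid.origin_year,
            "tau_max": bundle.grid.tau_max,
            "to_date_months": bundle.grid.to_date_months,
            "proj1_months": bundle.grid.proj1_months,
            "proj2_months": bundle.grid.proj2_months,
        },
        "population": "population.csv",
        "baseline_series": "baseline_deaths.csv",
        "age_distribution": "age_distribution.csv",
        "coverage": "coverage.csv",
        "diseases": [],
    }
    if obs_rows:
        doc["survival_observations"] = "survival_observations.csv"
    for d in bundle.diseases:
        entry: dict = {
            "id": d.id,
            "kind": d.kind,
            "phi_incidence": d.phi_incidence,
            "phi_cfr": d.phi_cfr,
            "baseline_scale": d.baseline_scale,
            "hazards": {
                arm: [
                    {"family": m.family, "unit": "per_month", "bound": m.bound,
                     "params": dict(m.params)}
                    for m in models
                ]
                for arm, models in d.hazards.items()
            },
        }
        if d.mean_incidence is not None:
            entry["mean_incidence"] = d.mean_incidence
        if d.calibration_k is not None:
            entry["calibration_k"] = d.calibration_k
        if d.prevalent_pool_size is not None:
            entry["prevalent_pool_size"] = d.prevalent_pool_size
        if d.acute is not None:
            entry["acute"] = {"treated": d.acute.treated, "untreated": d.acute.untreated}
        doc["diseases"].append(entry)

    config_path = outdir / "config.yaml"
    with open(config_path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return config_path


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_bundle(bundle: ScenarioBundle) -> list[str]:
    """Check bundle invariants; returns violation messages (empty = valid).

    Treatment-benefit checks (untreated hazard >= treated) are reported at
    warning level, prefixed "warning:", since they flag implausible rather
    than structurally invalid inputs.
    """
    v: list[str] = []
    ids = [d.id for d in bundle.diseases]
    if len(set(ids)) != len(ids):
        v.append(f"duplicate disease ids: {sorted(ids)}")
    known = set(ids)

    if bundle.n_runs < 1:
        v.append(f"n_runs must be >= 1, got {bundle.n_runs}")

    for stratum, count in bundle.population.counts.items():
        if count < 0:
            v.append(f"population count for stratum {stratum!r} is negative")
    strata = list(bundle.population.counts)
    if len(set(strata)) != len(strata):
        v.append("population strata are not unique")

    for (d, p, s), (lo, hi) in bundle.coverage.ranges.items():
        if d not in known:
            v.append(f"coverage references unknown disease {d!r}")
        if not (0.0 <= lo <= hi <= 1.0):
            v.append(
                f"coverage range ({lo}, {hi}) for {d}/{p}/{s} violates 0 <= lo <= hi <= 1"
            )

    for d in bundle.diseases:
        total = d.age_dist.total
        if abs(total - 1.0) > 1e-9:
            v.append(
                f"age distribution not normalised for {d.id} (sums to {total:.6f})"
            )
        if d.phi_incidence <= 0 or d.phi_cfr <= 0:
            v.append(f"phi multipliers for {d.id} must be > 0")
        # treatment benefit: untreated monthly death prob should dominate
        check_tau = np.array([1.0, 12.0, 60.0, 120.0])
        check_tau = check_tau[check_tau <= bundle.grid.tau_max]
        if len(check_tau):
            tau_max = int(check_tau.max())
            q_t = arm_death_prob_grid(d.hazards["treated"], tau_max, w=0.5)
            q_u = arm_death_prob_grid(d.hazards["untreated"], tau_max, w=0.5)
            idx = check_tau.astype(int)
            if np.any(q_u[idx] < q_t[idx] - 1e-12):
                bad = check_tau[q_u[idx] < q_t[idx] - 1e-12]
                v.append(
                    f"warning: treated hazard exceeds untreated for {d.id} "
                    f"at tau = {bad.astype(int).tolist()} months"
                )
    return v


# ---------------------------------------------------------------------------
# Output tables
# ---------------------------------------------------------------------------

def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero upward (1679.6 -> 1680)."""
    return int(Decimal(repr(float(x))).quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def format_count(x: float) -> str:
    """Report-style integer with thousands separators: 1679.6 -> '1,680'."""
    return f"{round_half_up(x):,}"


def write_tables(summary, destination: str | Path) -> list[Path]:
    """Write the three output tables for an :class:`ExcessSummary`.

    Produces excess deaths by disease x scenario x sub-period, by age
    stratum x scenario x sub-period, and the monthly death trajectories,
    with means and 2.5th/97.5th percentiles rounded half-up at write time.
    """
    dest = Path(destination)
    dest.mkdir(parents=True, exist_ok=True)
    table = summary.table
    if table is None or not len(table):
        raise ValueError("nothing to write: summary is empty")

    stat_cols = ["mean", "pi_lo", "pi_hi", "mean_crisis", "mean_counterfactual"]

    def _formatted(df: pd.DataFrame) -> pd.DataFrame:
        out = df.copy()
        for col in stat_cols:
            if col in out:
                out[col] = out[col].map(
                    lambda v: "" if pd.isna(v) else format_count(v)
                )
        return out

    by_disease = table[table.stratum == "all"].drop(columns=["stratum"])
    by_age = table[(table.disease == "all") & (table.stratum != "all")].drop(
        columns=["disease"]
    )
    paths = []
    for name, df in (
        ("excess_by_disease.csv", _formatted(by_disease)),
        ("excess_by_age.csv", _formatted(by_age)),
    ):
        p = dest / name
        df.to_csv(p, index=False)
        paths.append(p)

    monthly = summary.monthly.copy()
    for col in ("mean_crisis", "mean_counterfactual", "mean_excess"):
        monthly[col] = monthly[col].round(2)
    p = dest / "monthly_deaths.csv"
    monthly.to_csv(p, index=False)
    paths.append(p)
    return paths
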