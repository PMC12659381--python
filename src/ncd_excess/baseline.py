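"""Counterfactual (no-crisis) baseline mortality forecasts.

Annual pre-war death counts per disease are fitted with a Poisson GLM
(log link, calendar year as the single predictor) and extrapolated into
the analysis period, discretised to monthly increments.  Deaths are
allocated across age strata using the pre-war age distribution of deaths
for each disease, which is assumed unchanged by the crisis.

Forecasts are deterministic point forecasts: projection uncertainty is
propagated through treatment coverage and survival-curve bounds in the
cohort engine, not through the GLM.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import statsmodels.api as sm

__all__ = [
    "BaselineSeries",
    "AgeDistribution",
    "BaselineTrend",
    "fit_baseline_trend",
    "forecast_monthly_baseline",
    "allocate_by_age",
    "split_stroke",
]


@dataclass(frozen=True, eq=False)
class BaselineSeries:
    """Annual death counts for one disease."""

    disease: str
    years: tuple[int, ...]
    deaths: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.years) != len(self.deaths):
            raise ValueError("years and deaths must have equal length")
        if len(self.years) == 0:
            raise ValueError("empty baseline series")
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        object.__setattr__(self, "deaths", tuple(float(d) for d in self.deaths))
        if any(d < 0 for d in self.deaths):
            raise ValueError(f"negative death count in series for {self.disease}")
        diffs = np.diff(self.years)
        if len(diffs) and not np.all(diffs == 1):
            raise ValueError(f"years must be consecutive for {self.disease}")
        if len(self.years) == 1:
            warnings.warn(
                f"single-year baseline series for {self.disease}: "
                "forecast will be flat",
                stacklevel=2,
            )

    def __eq__(self, other) -> bool:  # value equality for bundle round-trips
        return (
            isinstance(other, BaselineSeries)
            and self.disease == other.disease
            and self.years == other.years
            and self.deaths == other.deaths
        )


@dataclass(frozen=True, eq=False)
class AgeDistribution:
    """Pre-war age distribution of deaths p_a for one disease."""

    disease: str
    shares: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "shares", dict(self.shares))
        if any(v < 0 for v in self.shares.values()):
            raise ValueError(f"negative age share for {self.disease}")

    @property
    def total(self) -> float:
        return float(sum(self.shares.values()))

    def is_normalised(self, tol: float = 1e-9) -> bool:
        return abs(self.total - 1.0) <= tol

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, AgeDistribution)
            and self.disease == other.disease
            and dict(self.shares) == dict(other.shares)
        )


@dataclass(frozen=True)
class BaselineTrend:
    """Poisson log-linear year trend: rate(year) = exp(a + b*(year-year0))."""

    year0: int
    intercept: float
    slope: float
    zero: bool = False  # all-zero series: forecast identically 0

    def annual_rate(self, year: int | np.ndarray):
        if self.zero:
            return np.zeros(np.shape(year)) if np.ndim(year) else 0.0
        out = np.exp(self.intercept + self.slope * (np.asarray(year) - self.year0))
        return out if np.ndim(year) else float(out)


def fit_baseline_trend(series: BaselineSeries) -> BaselineTrend:
    """Poisson GLM of annual deaths on calendar year (centred at first year).

    With exactly two years the fit interpolates both counts exactly; a
    single-year series yields a flat trend.
    """
    years = np.asarray(series.years, dtype=float)
    deaths = np.asarray(series.deaths, dtype=float)
    year0 = int(series.years[0])

    if np.all(deaths == 0):
        return BaselineTrend(year0=year0, intercept=-np.inf, slope=0.0, zero=True)
    if len(years) == 1:
        return BaselineTrend(year0=year0, intercept=math.log(deaths[0]), slope=0.0)

    x = sm.add_constant(years - year0)
    fit = sm.GLM(deaths, x, family=sm.families.Poisson()).fit()
    return BaselineTrend(
        year0=year0, intercept=float(fit.params[0]), slope=float(fit.params[1])
    )


def forecast_monthly_baseline(trend: BaselineTrend, grid, horizon_months: int) -> np.ndarray:
    """Monthly counterfactual deaths for months 0..horizon-1 of the grid.

    Each month takes one twelfth of the fitted annual rate of the
    calendar year containing the month's start day (months run 7th to
    6th, so a month belongs to the year its 7th falls in).
    """
    if horizon_months <= 0:
        raise ValueError(f"horizon must be positive, got {horizon_months}")
    months = np.arange(horizon_months)
    years = grid.year_of_month(months)
    return np.asarray(trend.annual_rate(years)) / 12.0


def allocate_by_age(deaths: float, dist: AgeDistribution) -> dict[str, float]:
    """Distribute deaths across age strata proportionally to p_a."""
    if not dist.is_normalised():
        raise ValueError(
            f"age distribution for {dist.disease} not normalised "
            f"(sums to {dist.total:.6f})"
        )
    return {stratum: deaths * share for stratum, share in dist.shares.items()}


def split_stroke(
    series: BaselineSeries, ischaemic_share: float = 0.5
) -> tuple[BaselineSeries, BaselineSeries]:
    """Split a combined stroke series into ischaemic/haemorrhagic (default 50/50)."""
    if not 0.0 <= ischaemic_share <= 1.0:
        raise ValueError("ischaemic_share must be in [0,1]")
    isch = BaselineSeries(
        disease=f"{series.disease}_ischaemic",
        years=series.years,
        deaths=tuple(d * ischaemic_share for d in series.deaths),
    )
    haem = BaselineSeries(
        disease=f"{series.disease}_haemorrhagic",
        years=series.years,
        deaths=tuple(d * (1.0 - ischaemic_share) for d in series.deaths),
    )
    return isch, haem
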