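"""Parametric hazard/survival models and maximum-likelihood fitting.

Four candidate hazard families (exponential, Weibull, log-normal,
log-logistic) describe case fatality as a function of time since disease
onset tau, measured in months.  Survival observations digitised from
cohort studies -- the proportion of a cohort still alive at reported
follow-up times -- are fitted by maximising an independent-binomial
likelihood at each time point, and the best-fitting family is selected
by raw log-likelihood (AIC selection is available but off by default).

For cardiovascular disease an immediate acute case-fatality risk
``mu_acute`` applies at first presentation; long-term survival curves
that include acute deaths are conditioned on acute-event survival by
dividing through by ``1 - mu_acute`` before fitting.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import optimize
from scipy.special import log_ndtr, xlogy

__all__ = [
    "FAMILIES",
    "HazardModel",
    "SurvivalObservation",
    "AcuteRisk",
    "FitError",
    "hazard_at",
    "survival_at",
    "log_survival_at",
    "discrete_death_prob",
    "condition_on_acute_survival",
    "fit_survival_model",
]

FAMILIES = ("exponential", "weibull", "lognormal", "loglogistic")

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "lognormal": ("mu", "sigma"),
    "loglogistic": ("alpha", "beta"),
}

#: parameters that must be strictly positive (log-normal ``mu`` is a free real)
_POSITIVE = {"rate", "shape", "scale", "sigma", "alpha", "beta"}


class FitError(RuntimeError):
    """Raised when no optimiser start converges to a finite likelihood."""


@dataclass(frozen=True)
class HazardModel:
    """One parametric hazard family for one disease x treatment arm.

    Parameters are in per-month time units: rates are per month, scale
    parameters (Weibull ``scale``, log-logistic ``alpha``) are months and
    the log-normal ``mu`` is log-months.
    """

    family: str
    params: Mapping[str, float]
    arm: str = "treated"  # treated | untreated
    bound: str = "point"  # point | lower | upper (bound on the survival curve)

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown hazard family {self.family!r}")
        expected = PARAM_NAMES[self.family]
        got = tuple(sorted(self.params))
        if got != tuple(sorted(expected)):
            raise ValueError(
                f"{self.family} expects parameters {expected}, got {got}"
            )
        for name, value in self.params.items():
            if not np.isfinite(value):
                raise ValueError(f"parameter {name} is not finite")
            if name in _POSITIVE and value <= 0:
                raise ValueError(f"parameter {name} must be > 0, got {value}")
        if self.arm not in ("treated", "untreated"):
            raise ValueError(f"arm must be treated|untreated, got {self.arm!r}")
        if self.bound not in ("point", "lower", "upper"):
            raise ValueError(f"bound must be point|lower|upper, got {self.bound!r}")
        # normalise to a plain dict so equality/round-trips are stable
        object.__setattr__(self, "params", dict(self.params))


@dataclass(frozen=True)
class SurvivalObservation:
    """Proportion of a cohort surviving to a reported follow-up time."""

    tau: float  # months since onset, > 0
    surviving: float  # proportion in [0, 1]
    n_eff: int | None = None  # effective cohort size behind the proportion
    arm: str = "treated"
    source: str = ""

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError(f"tau must be > 0, got {self.tau}")
        if not 0.0 <= self.surviving <= 1.0:
            raise ValueError(f"surviving must be in [0,1], got {self.surviving}")
        if self.n_eff is not None and self.n_eff <= 0:
            raise ValueError(f"n_eff must be positive, got {self.n_eff}")


@dataclass(frozen=True)
class AcuteRisk:
    """Probability of death at the first acute event, by treatment arm."""

    treated: float
    untreated: float

    def __post_init__(self) -> None:
        for name, p in (("treated", self.treated), ("untreated", self.untreated)):
            if not 0.0 <= p < 1.0:
                raise ValueError(f"acute risk {name} must be in [0,1), got {p}")
        if self.untreated < self.treated:
            warnings.warn(
                "untreated acute risk below treated acute risk "
                f"({self.untreated} < {self.treated})",
                stacklevel=2,
            )

    def for_arm(self, arm: str) -> float:
        if arm == "treated":
            return self.treated
        if arm == "untreated":
            return self.untreated
        raise ValueError(f"unknown arm {arm!r}")


_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)


def _log_sf_arr(family: str, params: Mapping[str, float], tau: np.ndarray) -> np.ndarray:
    """log S(tau) for tau >= 0 from the closed-form survival functions."""
    if family == "exponential":
        return -params["rate"] * tau
    if family == "weibull":
        return -((tau / params["scale"]) ** params["shape"])
    if family == "lognormal":
        with np.errstate(divide="ignore"):
            z = (np.log(tau) - params["mu"]) / params["sigma"]
        return log_ndtr(-z)  # log(1 - Phi(z))
    if family == "loglogistic":
        return -np.log1p((tau / params["alpha"]) ** params["beta"])
    raise AssertionError(family)


def hazard_at(model: HazardModel, tau):
    """Instantaneous death hazard (per month) at time-since-onset ``tau`` > 0."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau <= 0):
        raise ValueError("tau must be > 0 for hazard evaluation")
    p = model.params
    if model.family == "exponential":
        out = np.full(tau.shape, p["rate"])
    elif model.family == "weibull":
        k, s = p["shape"], p["scale"]
        out = (k / s) * (tau / s) ** (k - 1.0)
    elif model.family == "lognormal":
        # phi(z) / (sigma * tau * (1 - Phi(z)))  -- evaluated in log space
        z = (np.log(tau) - p["mu"]) / p["sigma"]
        log_pdf = -0.5 * z * z - _LOG_SQRT_2PI
        with np.errstate(over="ignore"):
            out = np.exp(log_pdf - np.log(p["sigma"] * tau) - log_ndtr(-z))
    elif model.family == "loglogistic":
        a, b = p["alpha"], p["beta"]
        r = (tau / a) ** b
        out = (b / tau) * r / (1.0 + r)
    else:
        raise AssertionError(model.family)
    return out if out.ndim else float(out)


def log_survival_at(model: HazardModel, tau):
    """log S(tau); vectorised, defined for tau >= 0 with log S(0) = 0."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0 for survival evaluation")
    out = _log_sf_arr(model.family, model.params, tau)
    return out if out.ndim else float(out)


def survival_at(model: HazardModel, tau):
    """Proportion surviving to ``tau`` months since onset; S(0) = 1."""
    out = np.exp(log_survival_at(model, tau))
    return out if np.ndim(out) else float(out)


def discrete_death_prob(model: HazardModel, tau):
    """Probability of dying within the month [tau, tau+1): 1 - S(tau+1)/S(tau)."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    ls0 = _log_sf_arr(model.family, model.params, tau)
    ls1 = _log_sf_arr(model.family, model.params, tau + 1.0)
    with np.errstate(invalid="ignore"):
        q = -np.expm1(ls1 - ls0)
    # S(tau) underflowed to 0: the cohort is numerically extinct there
    q = np.where(np.isneginf(ls0), 1.0, q)
    q = np.clip(q, 0.0, 1.0)
    return q if q.ndim else float(q)


def condition_on_acute_survival(
    obs: Sequence[SurvivalObservation], acute: AcuteRisk, arm: str
) -> list[SurvivalObservation]:
    """Divide overall survival by (1 - mu_acute) to get post-acute survival.

    Digitised CVD survival curves include deaths at the acute event; the
    cohort engine applies ``mu_acute`` separately at onset, so fitted
    long-term hazards must describe survival conditional on surviving it.
    """
    mu = acute.for_arm(arm)
    if mu >= 1.0:
        raise ValueError("mu_acute = 1 leaves no post-acute cohort to condition on")
    out = []
    for o in obs:
        s = o.surviving / (1.0 - mu)
        if s > 1.0 + 1e-12:
            raise ValueError(
                f"observed survival {o.surviving} at tau={o.tau} exceeds "
                f"1 - mu_acute = {1.0 - mu}: inconsistent acute risk"
            )
        out.append(replace(o, surviving=min(s, 1.0)))
    return out


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

def _theta_to_params(family: str, theta: np.ndarray) -> dict[str, float]:
    # positive parameters are optimised on the log scale; lognormal mu is free
    if family == "exponential":
        return {"rate": math.exp(theta[0])}
    if family == "weibull":
        return {"shape": math.exp(theta[0]), "scale": math.exp(theta[1])}
    if family == "lognormal":
        return {"mu": theta[0], "sigma": math.exp(theta[1])}
    if family == "loglogistic":
        return {"alpha": math.exp(theta[0]), "beta": math.exp(theta[1])}
    raise AssertionError(family)


def binomial_log_likelihood(
    family: str, params: Mapping[str, float], tau: np.ndarray, x: np.ndarray, n: np.ndarray
) -> float:
    """Sum over time points of x*ln S + (n-x)*ln(1-S)."""
    with np.errstate(over="ignore"):
        s = np.exp(_log_sf_arr(family, params, tau))
    s = np.clip(s, 1e-12, 1.0 - 1e-12)
    return float(np.sum(xlogy(x, s) + xlogy(n - x, 1.0 - s)))


def _start_grid(family: str, tau: np.ndarray, s_obs: np.ndarray) -> list[np.ndarray]:
    """Deterministic multi-start grid anchored on a crude exponential rate."""
    s_c = np.clip(s_obs, 1e-6, 1.0 - 1e-6)
    lam = float(np.mean(-np.log(s_c) / tau))
    lam = max(lam, 1e-8)
    scale = 1.0 / lam  # crude characteristic survival time, months
    shapes = (0.5, 1.0, 2.0)
    mults = (0.25, 1.0, 4.0)
    starts: list[np.ndarray] = []
    if family == "exponential":
        for m in mults:
            starts.append(np.array([math.log(lam * m)]))
    elif family == "weibull":
        for k in shapes:
            for m in mults:
                starts.append(np.array([math.log(k), math.log(scale * m)]))
    elif family == "lognormal":
        for sig in shapes:
            for m in mults:
                starts.append(np.array([math.log(scale * m), math.log(sig)]))
    elif family == "loglogistic":
        for b in shapes:
            for m in mults:
                starts.append(np.array([math.log(scale * m), math.log(b)]))
    return starts


def _fit_family(
    family: str, tau: np.ndarray, x: np.ndarray, n: np.ndarray, tol: float
) -> tuple[dict[str, float], float]:
    s_obs = x / n

    def neg_ll(theta: np.ndarray) -> float:
        try:
            params = _theta_to_params(family, theta)
        except OverflowError:
            return np.inf
        ll = binomial_log_likelihood(family, params, tau, x, n)
        return -ll if np.isfinite(ll) else np.inf

    best: tuple[float, np.ndarray] | None = None
    for theta0 in _start_grid(family, tau, s_obs):
        res = optimize.minimize(
            neg_ll,
            theta0,
            method="Nelder-Mead",
            options={"fatol": tol, "xatol": 1e-10, "maxiter": 2000},
        )
        if np.isfinite(res.fun) and (best is None or res.fun < best[0]):
            best = (res.fun, res.x)
    if best is None:
        raise FitError(
            f"no optimiser start converged for family {family!r} "
            f"(tau={tau.tolist()}, surviving={s_obs.tolist()})"
        )
    # gradient-based polish from the simplex optimum
    res = optimize.minimize(neg_ll, best[1], method="BFGS", options={"gtol": 1e-10})
    if np.isfinite(res.fun) and res.fun <= best[0]:
        best = (res.fun, res.x)
    params = _theta_to_params(family, best[1])
    return params, -best[0]


def fit_survival_model(
    obs: Sequence[SurvivalObservation],
    families: Iterable[str] = FAMILIES,
    *,
    n_eff_default: int = 100,
    selection: str = "loglik",
    tol: float = 1e-8,
) -> list[tuple[HazardModel, float]]:
    """Fit candidate hazard families to survival observations.

    Each observation contributes an independent binomial term with
    ``x = round(n_eff * surviving)`` survivors out of ``n_eff``; sources
    reporting no cohort size get ``n_eff_default``.  Returns the fitted
    models ranked best-first (by log-likelihood, or by AIC when
    ``selection="aic"``), each paired with its log-likelihood.

    Two-parameter families need at least two distinct follow-up times and
    are skipped (with a warning) otherwise.
    """
    if not obs:
        raise ValueError("at least one survival observation is required")
    families = tuple(families)
    if not families:
        raise ValueError("at least one candidate family is required")
    for f in families:
        if f not in FAMILIES:
            raise ValueError(f"unknown family {f!r}")
    arms = {o.arm for o in obs}
    if len(arms) > 1:
        raise ValueError(f"observations mix treatment arms: {sorted(arms)}")
    arm = obs[0].arm

    tau = np.array([o.tau for o in obs], dtype=float)
    n = np.array(
        [o.n_eff if o.n_eff is not None else n_eff_default for o in obs], dtype=float
    )
    x = np.round(n * np.array([o.surviving for o in obs]))

    results: list[tuple[HazardModel, float]] = []
    n_distinct = len(np.unique(tau))
    for family in families:
        if len(PARAM_NAMES[family]) > 1 and n_distinct < 2:
            warnings.warn(
                f"family {family!r} needs >= 2 distinct follow-up times; skipped",
                stacklevel=2,
            )
            continue
        params, ll = _fit_family(family, tau, x, n, tol)
        results.append((HazardModel(family, params, arm=arm), ll))
    if not results:
        raise FitError("no candidate family could be fitted to these observations")

    if selection == "aic":
        key = lambda item: 2 * len(item[0].params) - 2 * item[1]  # noqa: E731
        results.sort(key=key)
    elif selection == "loglik":
        results.sort(key=lambda item: -item[1])
    else:
        raise ValueError(f"selection must be 'loglik' or 'aic', got {selection!r}")
    return results
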