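"""Hazard/survival closed forms, consistency, conditioning and ML fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ncd_excess import (
    AcuteRisk,
    HazardModel,
    SurvivalObservation,
    condition_on_acute_survival,
    discrete_death_prob,
    fit_survival_model,
    hazard_at,
    survival_at,
)
from ncd_excess.survival import binomial_log_likelihood, log_survival_at

MODELS = [
    HazardModel("exponential", {"rate": 0.02}),
    HazardModel("weibull", {"shape": 1.4, "scale": 40.0}),
    HazardModel("lognormal", {"mu": 3.2, "sigma": 1.1}),
    HazardModel("loglogistic", {"alpha": 36.0, "beta": 1.5}),
]


@pytest.mark.parametrize(
    "model, tau, expected",
    [
        (HazardModel("exponential", {"rate": 0.02}), 7.0, 0.02),
        # standard-normal pdf(0)/(1 - cdf(0)) at tau = 1 (z = 0, sigma*tau = 1)
        (HazardModel("lognormal", {"mu": 0.0, "sigma": 1.0}), 1.0, 0.7978845608),
        # beta = 1 log-logistic: (1/alpha) / (1 + tau/alpha)
        (HazardModel("loglogistic", {"alpha": 10.0, "beta": 1.0}), 10.0, 0.05),
    ],
)
def test_hazard_closed_forms(model, tau, expected):
    assert hazard_at(model, tau) == pytest.approx(expected, rel=1e-8)


def test_hazard_rejects_nonpositive_tau():
    with pytest.raises(ValueError):
        hazard_at(MODELS[0], 0.0)
    with pytest.raises(ValueError):
        hazard_at(MODELS[0], -3.0)


def test_invalid_params_rejected():
    with pytest.raises(ValueError):
        HazardModel("exponential", {"rate": -0.1})
    with pytest.raises(ValueError):
        HazardModel("weibull", {"shape": 0.0, "scale": 10.0})
    with pytest.raises(ValueError):
        HazardModel("lognormal", {"mu": 0.0})  # missing sigma


def test_survival_closed_form_and_origin():
    model = HazardModel("exponential", {"rate": 0.05})
    assert survival_at(model, 12.0) == pytest.approx(math.exp(-0.6), rel=1e-12)
    for m in MODELS:
        assert survival_at(m, 0.0) == 1.0


@pytest.mark.parametrize("model", MODELS, ids=lambda m: m.family)
def test_hazard_is_negative_log_survival_derivative(model):
    """mu(tau) = -d ln S / d tau, checked by central finite difference."""
    tau, h = 24.0, 1e-5
    num = -(log_survival_at(model, tau + h) - log_survival_at(model, tau - h)) / (2 * h)
    assert num == pytest.approx(hazard_at(model, tau), rel=1e-6, abs=1e-9)


def test_weibull_shape_one_is_exponential():
    lam = 0.03
    weib = HazardModel("weibull", {"shape": 1.0, "scale": 1.0 / lam})
    expo = HazardModel("exponential", {"rate": lam})
    tau = np.array([0.5, 1.0, 12.0, 120.0, 500.0])
    assert np.allclose(hazard_at(weib, tau), hazard_at(expo, tau), atol=1e-12)


def test_discrete_death_prob_exponential_constant():
    model = HazardModel("exponential", {"rate": 0.05})
    q = discrete_death_prob(model, np.array([0.0, 3.0, 77.0]))
    assert np.allclose(q, 1 - math.exp(-0.05), rtol=1e-12)
    tiny = HazardModel("exponential", {"rate": 1e-12})
    assert discrete_death_prob(tiny, 5.0) < 1e-10  # vanishing-hazard limit


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    family=st.sampled_from(["exponential", "weibull", "lognormal", "loglogistic"]),
    p1=st.floats(0.05, 5.0),
    p2=st.floats(0.2, 3.0),
    tau=st.floats(0.0, 300.0),
)
def test_survival_monotone_and_death_prob_bounded(family, p1, p2, tau):
    """S is non-increasing with values in (0,1]; q = 1 - S(t+1)/S(t) in [0,1]."""
    params = {
        "exponential": {"rate": p1 / 10},
        "weibull": {"shape": p2, "scale": p1 * 20},
        "lognormal": {"mu": math.log(p1 * 20), "sigma": p2},
        "loglogistic": {"alpha": p1 * 20, "beta": p2},
    }[family]
    m = HazardModel(family, params)
    s0, s1 = survival_at(m, tau), survival_at(m, tau + 1.0)
    # S is strictly positive mathematically but may underflow far in the tail
    assert 0.0 <= s0 <= 1.0
    assert s1 <= s0 + 1e-15
    q = discrete_death_prob(m, tau)
    assert 0.0 <= q <= 1.0


def test_conditioning_identity_and_rescale():
    acute = AcuteRisk(treated=0.0, untreated=0.10)
    obs = [SurvivalObservation(tau=12.0, surviving=0.45)]
    assert condition_on_acute_survival(obs, acute, "treated")[0].surviving == 0.45
    out = condition_on_acute_survival(
        [SurvivalObservation(tau=12.0, surviving=0.45, arm="untreated")],
        acute,
        "untreated",
    )
    assert out[0].surviving == pytest.approx(0.5)


def test_conditioning_rejects_inconsistent_data():
    acute = AcuteRisk(treated=0.10, untreated=0.10)
    obs = [SurvivalObservation(tau=6.0, surviving=0.95)]
    with pytest.raises(ValueError, match="acute"):
        condition_on_acute_survival(obs, acute, "treated")


def test_single_point_exponential_fit_is_exact():
    """One binomial point pins S(12) = 0.5, so lambda = ln 2 / 12."""
    obs = [SurvivalObservation(tau=12.0, surviving=0.5)]
    (model, ll), = fit_survival_model(obs, families=["exponential"])
    assert model.params["rate"] == pytest.approx(math.log(2) / 12, rel=1e-5)


def test_loglogistic_recovery_and_family_selection():
    """Noise-free points from a log-logistic rank it first and recover params."""
    true = HazardModel("loglogistic", {"alpha": 36.0, "beta": 1.5})
    taus = [3.0, 6.0, 12.0, 24.0, 48.0, 96.0, 150.0, 250.0]
    obs = [
        SurvivalObservation(tau=t, surviving=float(survival_at(true, t)), n_eff=10000)
        for t in taus
    ]
    ranked = fit_survival_model(obs)
    best, _ = ranked[0]
    assert best.family == "loglogistic"
    assert best.params["alpha"] == pytest.approx(36.0, rel=0.01)
    assert best.params["beta"] == pytest.approx(1.5, rel=0.01)


def test_fitted_model_is_locally_optimal():
    """Log-likelihood at the optimum beats a +/-5% perturbation grid."""
    rng = np.random.default_rng(5)
    true = HazardModel("weibull", {"shape": 0.9, "scale": 50.0})
    taus = [6.0, 12.0, 24.0, 60.0, 120.0]
    n = 5000
    obs = [
        SurvivalObservation(
            tau=t, surviving=rng.binomial(n, survival_at(true, t)) / n, n_eff=n
        )
        for t in taus
    ]
    (model, ll) = fit_survival_model(obs, families=["weibull"])[0]
    tau_a = np.array(taus)
    n_a = np.full(len(taus), float(n))
    x_a = np.round(n_a * np.array([o.surviving for o in obs]))
    for f_shape in (0.95, 1.0, 1.05):
        for f_scale in (0.95, 1.0, 1.05):
            perturbed = {
                "shape": model.params["shape"] * f_shape,
                "scale": model.params["scale"] * f_scale,
            }
            ll_p = binomial_log_likelihood("weibull", perturbed, tau_a, x_a, n_a)
            assert ll + 1e-9 >= ll_p


def test_conditioned_fit_reproduces_overall_survival():
    """Fit post-acute survival, multiply back by 1 - mu_acute: overall curve."""
    acute = AcuteRisk(treated=0.10, untreated=0.30)
    post = HazardModel("exponential", {"rate": 0.02})
    taus = [6.0, 12.0, 36.0, 72.0]
    overall = [
        SurvivalObservation(
            tau=t, surviving=0.9 * float(survival_at(post, t)), n_eff=10000
        )
        for t in taus
    ]
    conditioned = condition_on_acute_survival(overall, acute, "treated")
    (model, _), = fit_survival_model(conditioned, families=["exponential"])
    for o in overall:
        back = 0.9 * survival_at(model, o.tau)
        assert back == pytest.approx(o.surviving, rel=1e-3)


def test_two_parameter_families_skipped_on_single_time():
    obs = [SurvivalObservation(tau=12.0, surviving=0.5)]
    with pytest.warns(UserWarning, match="distinct follow-up"):
        ranked = fit_survival_model(obs, families=["exponential", "weibull"])
    assert [m.family for m, _ in ranked] == ["exponential"]
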