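"""Closed-form survival functions, censored MLE, and AIC/BIC selection."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from sclc_cea.survival import (
    FAMILIES,
    FitError,
    ParametricSurvival,
    fit_parametric,
    fit_report,
    fit_standard_errors,
    median_survival,
    select_model,
    survival_at,
)
from sclc_cea.synth import CensoringSpec, simulate_ipd

# representative valid parameter sets, used by the property tests
EXAMPLE_MODELS = {
    "exponential": {"rate": 0.08},
    "weibull": {"shape": 1.3, "scale": 14.0},
    "weibull_ph": {"shape": 1.3, "rate": 14.0 ** -1.3},
    "gamma": {"shape": 1.5, "rate": 0.1},
    "generalized_gamma": {"mu": 1.9133, "sigma": 0.6989, "Q": -0.7736},
    "gompertz": {"shape": 0.05, "rate": 0.04},
    "loglogistic": {"shape": 2.4470, "scale": 12.8850},
    "lognormal": {"meanlog": 2.9149, "sdlog": 0.9062},
}


def _random_model(family: str, rng: np.random.Generator) -> ParametricSurvival:
    base = EXAMPLE_MODELS[family]
    params = {}
    for name, value in base.items():
        factor = math.exp(rng.uniform(-0.7, 0.7))
        params[name] = value * factor if name != "Q" else rng.uniform(-1.5, 1.5)
    return ParametricSurvival(family, params)


# ---------------------------------------------------------------------------
# survival_at / median
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "family,params,t,expected",
    [
        # log-normal median is exp(meanlog); fitted OS parameters
        ("lognormal", {"meanlog": 2.9149, "sdlog": 0.9062}, math.exp(2.9149), 0.5),
        # log-logistic median is the scale parameter
        ("loglogistic", {"shape": 2.4470, "scale": 12.8850}, 12.8850, 0.5),
        ("exponential", {"rate": math.log(2)}, 1.0, 0.5),
        ("weibull", {"shape": 2.0, "scale": 10.0}, 0.0, 1.0),
    ],
)
def test_survival_at_known_points(family, params, t, expected):
    model = ParametricSurvival(family, params)
    assert survival_at(model, t) == pytest.approx(expected, abs=1e-10)


def test_gengamma_q_zero_limit_is_lognormal():
    gg = ParametricSurvival(
        "generalized_gamma", {"mu": 1.9133, "sigma": 0.6989, "Q": 1e-8}
    )
    ln = ParametricSurvival("lognormal", {"meanlog": 1.9133, "sdlog": 0.6989})
    t = np.linspace(0.01, 60, 200)
    np.testing.assert_allclose(gg.survival(t), ln.survival(t), atol=1e-6)


def test_gengamma_matches_flexsurv_reference():
    """Frozen values computed with R flexsurv::pgengamma (Prentice form)."""
    model = ParametricSurvival(
        "generalized_gamma", {"mu": 1.9133, "sigma": 0.6989, "Q": -0.7736}
    )
    t = np.array([2.0, 5.0, 12.0, 24.0, 60.0, 120.0])
    expected = np.array(
        [0.9932767, 0.7623562, 0.3196154, 0.1170042, 0.02520388, 0.007348574]
    )
    np.testing.assert_allclose(model.survival(t), expected, rtol=1e-6)


@pytest.mark.parametrize(
    "family,params,expected",
    [
        ("lognormal", {"meanlog": 2.9149, "sdlog": 0.9062}, math.exp(2.9149)),
        ("loglogistic", {"shape": 4.4280, "scale": 5.0570}, 5.0570),
        ("exponential", {"rate": math.log(2)}, 1.0),
    ],
)
def test_median_survival_closed_forms(family, params, expected):
    model = ParametricSurvival(family, params)
    assert median_survival(model) == pytest.approx(expected, rel=1e-10)


@pytest.mark.parametrize("family", FAMILIES)
def test_median_satisfies_definition(family):
    rng = np.random.default_rng(7)
    for _ in range(5):
        model = _random_model(family, rng)
        t_star = median_survival(model)
        assert abs(model.survival(t_star) - 0.5) < 1e-10


@pytest.mark.parametrize("family", FAMILIES)
def test_survival_shape_properties(family):
    """S(0)=1 exactly, S non-increasing, and S + F = 1 on a fine grid."""
    rng = np.random.default_rng(11)
    grid = np.linspace(0.0, 200.0, 1000)
    for _ in range(8):
        model = _random_model(family, rng)
        s = model.survival(grid)
        assert s[0] == 1.0
        assert np.all(np.diff(s) <= 1e-15)
        assert np.all((0.0 <= s) & (s <= 1.0))
        # CDF via the quantile inverse: F(quantile(p)) == p
        p = np.array([0.1, 0.5, 0.9])
        tq = model.quantile(p)
        np.testing.assert_allclose(1.0 - model.survival(tq), p, atol=1e-10)


def test_weibull_aft_and_ph_are_the_same_distribution():
    rng = np.random.default_rng(3)
    t = np.linspace(0.0, 80.0, 300)
    for _ in range(10):
        shape = rng.uniform(0.5, 3.0)
        scale = rng.uniform(2.0, 30.0)
        aft = ParametricSurvival("weibull", {"shape": shape, "scale": scale})
        ph = ParametricSurvival("weibull_ph", {"shape": shape, "rate": scale ** -shape})
        np.testing.assert_allclose(aft.survival(t), ph.survival(t), atol=1e-12)


def test_invalid_inputs_raise():
    with pytest.raises(ValueError):
        ParametricSurvival("lognormal", {"meanlog": 1.0, "sdlog": -1.0})
    with pytest.raises(ValueError):
        ParametricSurvival("nosuch", {"rate": 1.0})
    with pytest.raises(ValueError):
        ParametricSurvival("exponential", {"rate": 1.0}).survival(-1.0)


@given(
    rate=st.floats(0.01, 2.0),
    t=st.floats(0.0, 100.0),
)
def test_exponential_survival_closed_form(rate, t):
    model = ParametricSurvival("exponential", {"rate": rate})
    assert model.survival(t) == pytest.approx(math.exp(-rate * t), rel=1e-12)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def test_exponential_fit_matches_closed_form():
    """Events-only data: MLE rate is n/sum(t) and loglik matches it to 1e-6."""
    ipd = simulate_ipd(
        ParametricSurvival("exponential", {"rate": 0.11}), n=800, seed=5
    )
    fit = fit_parametric(ipd, "exponential")
    t = ipd["time_months"].to_numpy()
    rate_closed = len(t) / t.sum()
    assert fit.model.params["rate"] == pytest.approx(rate_closed, rel=1e-5)
    ll_closed = len(t) * math.log(rate_closed) - rate_closed * t.sum()
    assert fit.loglik == pytest.approx(ll_closed, abs=1e-6)


def test_aic_bic_identities():
    ipd = simulate_ipd(
        ParametricSurvival("exponential", {"rate": 0.2}), n=100, seed=2
    )
    fit = fit_parametric(ipd, "exponential")
    assert fit.k == 1
    assert fit.aic == pytest.approx(2 * fit.k - 2 * fit.loglik, abs=1e-12)
    assert fit.bic == pytest.approx(fit.k * math.log(100) - 2 * fit.loglik, abs=1e-12)
    assert fit.aic - fit.bic == pytest.approx(2 - math.log(100), abs=1e-12)


def test_loglogistic_parameter_recovery():
    """5,000 uncensored draws from the control-arm OS model."""
    true = ParametricSurvival("loglogistic", {"shape": 2.447, "scale": 12.885})
    ipd = simulate_ipd(true, n=5000, seed=42)
    fit = fit_parametric(ipd, "loglogistic")
    assert 2.35 <= fit.model.params["shape"] <= 2.55
    assert 12.4 <= fit.model.params["scale"] <= 13.4


@pytest.mark.parametrize("family", FAMILIES)
def test_parameter_recovery_within_3_se(family):
    """At n=5,000 each family recovers its generating parameters to 3 SE."""
    true = ParametricSurvival(family, EXAMPLE_MODELS[family])
    ipd = simulate_ipd(true, n=5000, seed=17)
    fit = fit_parametric(ipd, family)
    se = fit_standard_errors(fit, ipd)
    for name, value in true.params.items():
        err = abs(fit.model.params[name] - value)
        assert err < 3 * max(se[name], 1e-8), (
            f"{family}.{name}: |{fit.model.params[name]:.4f} - {value:.4f}| "
            f">= 3 x {se[name]:.4g}"
        )


def test_fit_is_start_invariant():
    """Different starting points reach the same maximized likelihood."""
    true = ParametricSurvival("weibull", {"shape": 1.4, "scale": 11.0})
    ipd = simulate_ipd(true, n=600, seed=9,
                       cens=CensoringSpec(administrative_cutoff=24.0))
    fit1 = fit_parametric(ipd, "weibull")
    fit2 = fit_parametric(ipd, "weibull", init={"shape": 3.0, "scale": 4.0})
    assert fit1.loglik == pytest.approx(fit2.loglik, abs=1e-6)


def test_censored_likelihood_uses_survival_term():
    """Heavier censoring must raise the fitted exponential rate estimate's
    loglik relative to treating censored times as events."""
    true = ParametricSurvival("exponential", {"rate": 0.1})
    ipd = simulate_ipd(true, n=500, seed=3,
                       cens=CensoringSpec(administrative_cutoff=8.0))
    assert (ipd["event"] == 0).any()
    fit = fit_parametric(ipd, "exponential")
    t, e = ipd["time_months"].to_numpy(), ipd["event"].to_numpy()
    rate_closed = e.sum() / t.sum()  # censored-exponential MLE
    assert fit.model.params["rate"] == pytest.approx(rate_closed, rel=1e-5)


def test_all_censored_raises():
    ipd = simulate_ipd(
        ParametricSurvival("exponential", {"rate": 0.001}), n=50, seed=1,
        cens=CensoringSpec(administrative_cutoff=0.5),
    )
    ipd["event"] = 0
    with pytest.raises(FitError):
        fit_parametric(ipd, "exponential")


def test_fit_against_lifelines_oracle():
    """Independent cross-check: lifelines' Weibull MLE on censored data."""
    from lifelines import WeibullFitter

    true = ParametricSurvival("weibull", {"shape": 1.6, "scale": 9.0})
    ipd = simulate_ipd(true, n=1500, seed=21,
                       cens=CensoringSpec(administrative_cutoff=18.0, dropout_rate=0.01))
    fit = fit_parametric(ipd, "weibull")
    wf = WeibullFitter().fit(ipd["time_months"], ipd["event"])
    assert fit.model.params["scale"] == pytest.approx(wf.lambda_, rel=1e-3)
    assert fit.model.params["shape"] == pytest.approx(wf.rho_, rel=1e-3)
    assert fit.loglik == pytest.approx(wf.log_likelihood_, abs=1e-3)


# ---------------------------------------------------------------------------
# selection
# ---------------------------------------------------------------------------


def test_select_model_single_family():
    ipd = simulate_ipd(ParametricSurvival("exponential", {"rate": 0.1}), 200, seed=4)
    ranked = select_model(ipd, ["exponential"])
    assert len(ranked) == 1 and ranked[0].model.family == "exponential"


def test_select_model_prefers_generating_family():
    """Large log-normal sample: log-normal or its gengamma superfamily wins."""
    ipd = simulate_ipd(
        ParametricSurvival("lognormal", {"meanlog": 2.0, "sdlog": 0.7}), 3000, seed=8
    )
    ranked = select_model(ipd)
    assert ranked[0].model.family in ("lognormal", "generalized_gamma")
    assert ranked == sorted(ranked, key=lambda r: (r.aic, r.bic, r.k))


def test_loglogistic_beats_exponential_on_loglogistic_data():
    ipd = simulate_ipd(
        ParametricSurvival("loglogistic", {"shape": 4.428, "scale": 5.057}), 2000, seed=6
    )
    ranked = {r.model.family: r for r in select_model(ipd, ["exponential", "loglogistic"])}
    assert ranked["loglogistic"].aic < ranked["exponential"].aic


def test_fit_report_keeps_failed_rows_as_nan():
    ipd = simulate_ipd(ParametricSurvival("exponential", {"rate": 0.1}), 30, seed=4)
    report = fit_report(ipd, ["exponential", "generalized_gamma"])
    assert "exponential" in report.index
    assert report.shape[0] == 2  # a failing family yields a NaN row, not an abort
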