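"""Parametric survival distributions for extrapolating trial endpoints.

Eight candidate families are supported, matching the set customarily fitted
to digitized oncology Kaplan-Meier curves before a partitioned-survival or
Markov model is built: exponential, Weibull (AFT and PH forms), gamma,
generalized gamma (Prentice), Gompertz, log-logistic and log-normal.  Time
is measured in months throughout.

The generalized gamma uses the Prentice (mu, sigma, Q) parameterization:
with ``w = (ln t - mu) / sigma`` and ``a = Q**-2``,

    S(t) = 1 - P(a, a * exp(Q w))   for Q > 0
    S(t) =     P(a, a * exp(Q w))   for Q < 0
    S(t) = 1 - Phi(w)               for Q = 0  (log-normal limit)

where P is the regularized lower incomplete gamma function.  Q may be any
real number; Q = 0 is handled as the log-normal limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, special, stats

__all__ = [
    "FAMILIES",
    "PARAM_NAMES",
    "ParametricSurvival",
    "FitResult",
    "FitError",
    "survival_at",
    "median_survival",
    "fit_parametric",
    "select_model",
]

FAMILIES = (
    "exponential",
    "weibull",
    "weibull_ph",
    "gamma",
    "generalized_gamma",
    "gompertz",
    "loglogistic",
    "lognormal",
)

PARAM_NAMES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "weibull_ph": ("shape", "rate"),
    "gamma": ("shape", "rate"),
    "generalized_gamma": ("mu", "sigma", "Q"),
    "gompertz": ("shape", "rate"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
}

# parameters that must be strictly positive; the rest are unconstrained reals
_POSITIVE: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "weibull_ph": ("shape", "rate"),
    "gamma": ("shape", "rate"),
    "generalized_gamma": ("sigma",),
    "gompertz": ("rate",),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("sdlog",),
}

_GG_Q_EPS = 1e-7  # below this |Q| the Prentice family is evaluated at its log-normal limit


class FitError(RuntimeError):
    """Raised when maximum-likelihood fitting cannot produce a usable result."""


@dataclass(frozen=True)
class ParametricSurvival:
    """A survival distribution family with fitted parameters (time in months)."""

    family: str
    params: dict[str, float]
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}; expected one of {FAMILIES}")
        expected = PARAM_NAMES[self.family]
        if tuple(self.params) != expected and set(self.params) != set(expected):
            raise ValueError(
                f"{self.family} expects parameters {expected}, got {tuple(self.params)}"
            )
        for name in _POSITIVE[self.family]:
            if not self.params[name] > 0:
                raise ValueError(f"{self.family} parameter {name!r} must be > 0")
        for name, value in self.params.items():
            if not math.isfinite(value):
                raise ValueError(f"{self.family} parameter {name!r} must be finite")

    # -- numerics ---------------------------------------------------------

    def survival(self, t):
        """S(t) for scalar or array t >= 0."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("survival time must be >= 0")
        s = _survival(self.family, self.params, t)
        return float(s) if np.isscalar(t) or t.ndim == 0 else s

    def log_density(self, t):
        """ln f(t) for t > 0 (used by the censored likelihood)."""
        t = np.asarray(t, dtype=float)
        if np.any(t <= 0):
            raise ValueError("event times must be > 0")
        return _log_density(self.family, self.params, t)

    def quantile(self, p):
        """t such that F(t) = p, in closed form for every family."""
        p = np.asarray(p, dtype=float)
        if np.any((p < 0) | (p >= 1)):
            raise ValueError("quantile level must be in [0, 1)")
        q = _quantile(self.family, self.params, p)
        return float(q) if p.ndim == 0 else q

    def median(self) -> float:
        return float(self.quantile(0.5))


def survival_at(model: ParametricSurvival, t) -> float:
    """Survival probability S(t) of ``model`` at time ``t`` (months)."""
    return model.survival(t)


def median_survival(model: ParametricSurvival) -> float:
    """Median survival time in months, |S(t*) - 0.5| < 1e-10."""
    t = model.median()
    if not math.isfinite(t) or abs(model.survival(t) - 0.5) > 1e-10:
        # closed forms cover all families; brentq is a safety net only
        hi = 1.0
        while model.survival(hi) > 0.5:
            hi *= 2.0
        t = optimize.brentq(lambda x: model.survival(x) - 0.5, 0.0, hi, xtol=1e-13)
    return float(t)


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------


def _survival(family: str, p: dict[str, float], t: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore", over="ignore", invalid="ignore"):
        if family == "exponential":
            s = np.exp(-p["rate"] * t)
        elif family == "weibull":
            s = np.exp(-((t / p["scale"]) ** p["shape"]))
        elif family == "weibull_ph":
            s = np.exp(-p["rate"] * t ** p["shape"])
        elif family == "gamma":
            s = special.gammaincc(p["shape"], p["rate"] * t)
        elif family == "gompertz":
            b, r = p["shape"], p["rate"]
            if abs(b) < 1e-12:
                s = np.exp(-r * t)
            else:
                s = np.exp(-(r / b) * np.expm1(b * t))
        elif family == "loglogistic":
            s = 1.0 / (1.0 + (t / p["scale"]) ** p["shape"])
        elif family == "lognormal":
            logt = np.log(np.where(t > 0, t, 1.0))
            s = np.where(t > 0, stats.norm.sf((logt - p["meanlog"]) / p["sdlog"]), 1.0)
        elif family == "generalized_gamma":
            s = _gengamma_sf(t, p["mu"], p["sigma"], p["Q"])
        else:  # pragma: no cover
            raise AssertionError(family)
    return np.clip(np.where(t == 0, 1.0, s), 0.0, 1.0)


def _gengamma_sf(t: np.ndarray, mu: float, sigma: float, q: float) -> np.ndarray:
    if abs(q) < _GG_Q_EPS:
        logt = np.log(np.where(t > 0, t, 1.0))
        return np.where(t > 0, stats.norm.sf((logt - mu) / sigma), 1.0)
    a = q ** -2
    logt = np.log(np.where(t > 0, t, 1.0))
    w = (logt - mu) / sigma
    u = a * np.exp(np.clip(q * w, -700.0, 700.0))
    sf = special.gammainc(a, u) if q < 0 else special.gammaincc(a, u)
    return np.where(t > 0, sf, 1.0)


def _log_density(family: str, p: dict[str, float], t: np.ndarray) -> np.ndarray:
    logt = np.log(t)
    if family == "exponential":
        return math.log(p["rate"]) - p["rate"] * t
    if family == "weibull":
        a, s = p["shape"], p["scale"]
        z = t / s
        return math.log(a / s) + (a - 1.0) * np.log(z) - z ** a
    if family == "weibull_ph":
        a, r = p["shape"], p["rate"]
        return math.log(r * a) + (a - 1.0) * logt - r * t ** a
    if family == "gamma":
        return stats.gamma.logpdf(t, p["shape"], scale=1.0 / p["rate"])
    if family == "gompertz":
        b, r = p["shape"], p["rate"]
        if abs(b) < 1e-12:
            return math.log(r) - r * t
        return math.log(r) + b * t - (r / b) * np.expm1(b * t)
    if family == "loglogistic":
        a, s = p["shape"], p["scale"]
        z = (t / s) ** a
        return math.log(a / s) + (a - 1.0) * np.log(t / s) - 2.0 * np.log1p(z)
    if family == "lognormal":
        return stats.norm.logpdf((logt - p["meanlog"]) / p["sdlog"]) - np.log(
            p["sdlog"]
        ) - logt
    if family == "generalized_gamma":
        mu, sigma, q = p["mu"], p["sigma"], p["Q"]
        if abs(q) < _GG_Q_EPS:
            return stats.norm.logpdf((logt - mu) / sigma) - np.log(sigma) - logt
        a = q ** -2
        w = (logt - mu) / sigma
        qw = np.clip(q * w, -700.0, 700.0)
        return (
            np.log(abs(q))
            + a * math.log(a)
            - math.lgamma(a)
            - np.log(sigma)
            - logt
            + a * (qw - np.exp(qw))
        )
    raise AssertionError(family)  # pragma: no cover


def _quantile(family: str, p: dict[str, float], prob: np.ndarray) -> np.ndarray:
    if family == "exponential":
        return -np.log1p(-prob) / p["rate"]
    if family == "weibull":
        return p["scale"] * (-np.log1p(-prob)) ** (1.0 / p["shape"])
    if family == "weibull_ph":
        return (-np.log1p(-prob) / p["rate"]) ** (1.0 / p["shape"])
    if family == "gamma":
        return stats.gamma.ppf(prob, p["shape"], scale=1.0 / p["rate"])
    if family == "gompertz":
        b, r = p["shape"], p["rate"]
        if abs(b) < 1e-12:
            return -np.log1p(-prob) / r
        arg = 1.0 - (b / r) * np.log1p(-prob)
        return np.where(arg > 0, np.log(np.maximum(arg, 1e-300)) / b, np.inf)
    if family == "loglogistic":
        return p["scale"] * (prob / (1.0 - prob)) ** (1.0 / p["shape"])
    if family == "lognormal":
        return np.exp(p["meanlog"] + p["sdlog"] * stats.norm.ppf(prob))
    if family == "generalized_gamma":
        mu, sigma, q = p["mu"], p["sigma"], p["Q"]
        if abs(q) < _GG_Q_EPS:
            return np.exp(mu + sigma * stats.norm.ppf(prob))
        a = q ** -2
        tail = prob if q < 0 else 1.0 - prob  # S(t)=P(a,u) if Q<0 else 1-P(a,u)
        u = special.gammaincinv(a, 1.0 - tail)
        w = np.log(u / a) / q
        return np.exp(mu + sigma * w)
    raise AssertionError(family)  # pragma: no cover


# ---------------------------------------------------------------------------
# maximum-likelihood fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitResult:
    """One family's MLE fit to right-censored data, with information criteria."""

    model: ParametricSurvival
    loglik: float
    n: int
    k: int = field(init=False)
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        k = len(self.model.params)
        object.__setattr__(self, "k", k)
        object.__setattr__(self, "aic", 2.0 * k - 2.0 * self.loglik)
        object.__setattr__(self, "bic", k * math.log(self.n) - 2.0 * self.loglik)


def _neg_loglik(family, theta, t_event, t_cens):
    params = _from_unconstrained(family, theta)
    try:
        model = ParametricSurvival(family, params)
    except ValueError:
        return np.inf
    ll = 0.0
    if t_event.size:
        ld = model.log_density(t_event)
        if not np.all(np.isfinite(ld)):
            return np.inf
        ll += float(np.sum(ld))
    if t_cens.size:
        s = np.maximum(_survival(family, params, t_cens), 1e-300)
        ll += float(np.sum(np.log(s)))
    return -ll if math.isfinite(ll) else np.inf


def _to_unconstrained(family: str, params: dict[str, float]) -> np.ndarray:
    pos = _POSITIVE[family]
    return np.array(
        [math.log(v) if name in pos else v for name, v in zip(PARAM_NAMES[family], (params[n] for n in PARAM_NAMES[family]))],
        dtype=float,
    )


def _from_unconstrained(family: str, theta: np.ndarray) -> dict[str, float]:
    pos = _POSITIVE[family]
    out = {}
    for name, v in zip(PARAM_NAMES[family], theta):
        out[name] = float(np.exp(np.clip(v, -700, 700))) if name in pos else float(v)
    return out


def _moment_start(family: str, times: np.ndarray) -> dict[str, float]:
    """Method-of-moments-style starting values from the observed times."""
    m = float(np.mean(times))
    logs = np.log(times)
    mlog, slog = float(np.mean(logs)), float(np.std(logs)) or 0.5
    v = float(np.var(times)) or m ** 2
    if family == "exponential":
        return {"rate": 1.0 / m}
    if family == "weibull":
        return {"shape": 1.2, "scale": m}
    if family == "weibull_ph":
        return {"shape": 1.2, "rate": m ** -1.2}
    if family == "gamma":
        shape = max(m ** 2 / v, 0.05)
        return {"shape": shape, "rate": shape / m}
    if family == "gompertz":
        return {"shape": 0.01, "rate": 1.0 / m}
    if family == "loglogistic":
        return {"shape": max(1.8 / slog, 0.2) * 1.0, "scale": math.exp(mlog)}
    if family == "lognormal":
        return {"meanlog": mlog, "sdlog": slog}
    if family == "generalized_gamma":
        return {"mu": mlog, "sigma": slog, "Q": 0.1}
    raise AssertionError(family)  # pragma: no cover


def fit_parametric(
    ipd,
    family: str,
    init: dict[str, float] | None = None,
    tol: float = 1e-8,
) -> FitResult:
    """Fit ``family`` to right-censored data by maximum likelihood.

    ``ipd`` is a DataFrame with columns ``time_months`` (> 0) and ``event``
    (1 = event, 0 = right-censored).  The censored log-likelihood
    ``sum_events ln f(t_i) + sum_censored ln S(t_i)`` is maximized by a
    quasi-Newton search on transformed (log for positive, identity for
    unconstrained) parameters, from multiple starting points: a moment-based
    start plus +/-50% perturbations, or ``init`` if supplied.

    Raises :class:`FitError` when no events are present or no start converges.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    t = np.asarray(ipd["time_months"], dtype=float)
    e = np.asarray(ipd["event"], dtype=int)
    if np.any(t <= 0):
        raise ValueError("times must be strictly positive")
    n = t.size
    k = len(PARAM_NAMES[family])
    if n < k + 2:
        raise FitError(f"need at least {k + 2} subjects to fit {family}")
    if not np.any(e == 1):
        raise FitError("all observations are censored; the likelihood is unbounded")
    t_event, t_cens = t[e == 1], t[e == 0]

    start = init if init is not None else _moment_start(family, t_event)
    theta0 = _to_unconstrained(family, start)
    starts = [theta0, theta0 * 0.5, theta0 * 1.5]
    # perturbing a zero coordinate does nothing; nudge it instead
    for s in starts[1:]:
        s[theta0 == 0.0] = 0.3

    best = None
    for theta in starts:
        res = optimize.minimize(
            lambda th: _neg_loglik(family, th, t_event, t_cens),
            theta,
            method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": tol, "xatol": 1e-10},
        )
        # quasi-Newton polish from the simplex optimum
        polish = optimize.minimize(
            lambda th: _neg_loglik(family, th, t_event, t_cens),
            res.x,
            method="BFGS",
            options={"gtol": 1e-10, "maxiter": 500},
        )
        cand = polish if polish.fun <= res.fun else res
        if math.isfinite(cand.fun) and (best is None or cand.fun < best.fun):
            best = cand
    if best is None or not math.isfinite(best.fun):
        raise FitError(f"{family} fit failed to converge from all starts")
    model = ParametricSurvival(family, _from_unconstrained(family, best.x))
    return FitResult(model=model, loglik=-float(best.fun), n=int(n))


def fit_standard_errors(fit: FitResult, ipd) -> dict[str, float]:
    """Asymptotic standard errors from the numerical Hessian at the MLE.

    Computed on the natural (untransformed) parameter scale via the delta
    method on the optimizer's transformed scale.
    """
    family = fit.model.family
    t = np.asarray(ipd["time_months"], dtype=float)
    e = np.asarray(ipd["event"], dtype=int)
    t_event, t_cens = t[e == 1], t[e == 0]
    theta = _to_unconstrained(family, fit.model.params)

    def nll(th):
        return _neg_loglik(family, th, t_event, t_cens)

    h = 1e-4
    p = theta.size
    hess = np.zeros((p, p))
    for i in range(p):
        for j in range(i, p):
            ei = np.zeros(p); ei[i] = h
            ej = np.zeros(p); ej[j] = h
            hess[i, j] = hess[j, i] = (
                nll(theta + ei + ej) - nll(theta + ei - ej)
                - nll(theta - ei + ej) + nll(theta - ei - ej)
            ) / (4 * h * h)
    cov = np.linalg.pinv(hess)
    se_t = np.sqrt(np.maximum(np.diag(cov), 0.0))
    pos = _POSITIVE[family]
    out = {}
    for idx, name in enumerate(PARAM_NAMES[family]):
        jac = fit.model.params[name] if name in pos else 1.0  # d(exp)/dtheta
        out[name] = float(se_t[idx] * abs(jac))
    return out


def select_model(ipd, families=FAMILIES) -> list[FitResult]:
    """Fit every family and rank ascending by AIC (ties: BIC, then fewer params).

    Families whose fit fails are silently dropped from the ranking (reported
    by the companion :func:`fit_report` as missing rows).
    """
    families = tuple(families)
    if len(families) < 1:
        raise ValueError("need at least one family")
    results: list[FitResult] = []
    for family in families:
        try:
            results.append(fit_parametric(ipd, family))
        except FitError:
            continue
    if not results:
        raise FitError("every candidate family failed to fit")
    results.sort(key=lambda r: (r.aic, r.bic, r.k))
    return results


def fit_report(ipd, families=FAMILIES):
    """AIC/BIC table across families (rows = family, columns = AIC, BIC).

    Families that fail to fit appear as NaN rows rather than aborting.
    """
    import pandas as pd

    rows = []
    for family in families:
        try:
            fr = fit_parametric(ipd, family)
            rows.append({"family": family, "aic": fr.aic, "bic": fr.bic,
                         "loglik": fr.loglik, "k": fr.k})
        except FitError:
            rows.append({"family": family, "aic": np.nan, "bic": np.nan,
                         "loglik": np.nan, "k": len(PARAM_NAMES[family])})
    return pd.DataFrame(rows).set_index("family")
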