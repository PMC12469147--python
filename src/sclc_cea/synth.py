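"""Synthetic two-arm trial data with the structure of a first-line ES-SCLC study.

The economic model's survival inputs were fitted to digitized Kaplan-Meier
curves; the underlying individual patient data (IPD) are not public.  This
module generates pseudo-IPD from the fitted parametric models so that the
survival-fitting stage of the pipeline can be exercised and validated
end-to-end: event times are drawn by inverse-CDF sampling, censoring is the
minimum of an administrative cutoff and exponential dropout, and a built-in
trial-sized fixture couples PFS <= OS within each subject.

All censoring settings here are synthetic: the source trial's follow-up and
censoring pattern are not reported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import ParametricSurvival

__all__ = ["CensoringSpec", "simulate_ipd", "trial_fixture", "km_estimate",
           "TRIAL_MODELS", "N_COMBO", "N_CONTROL"]

IPD_COLUMNS = ["id", "time_months", "event", "arm", "endpoint"]

#: fitted survival models for each arm/endpoint (time in months)
TRIAL_MODELS: dict[str, dict[str, ParametricSurvival]] = {
    "combo": {
        "OS": ParametricSurvival("lognormal", {"meanlog": 2.9149, "sdlog": 0.9062}),
        "PFS": ParametricSurvival(
            "generalized_gamma", {"mu": 1.9133, "sigma": 0.6989, "Q": -0.7736}
        ),
    },
    "control": {
        "OS": ParametricSurvival("loglogistic", {"shape": 2.4470, "scale": 12.8850}),
        "PFS": ParametricSurvival("loglogistic", {"shape": 4.4280, "scale": 5.0570}),
    },
}

# arm sizes implied by the reported second-line treatment counts/proportions
# (105/0.4268 and 176/0.7126 are integers only at 246 and 247)
N_COMBO = 246
N_CONTROL = 247


@dataclass(frozen=True)
class CensoringSpec:
    """Right-censoring: administrative cutoff plus exponential dropout.

    ``administrative_cutoff`` is in months (``inf`` disables it);
    ``dropout_rate`` is a per-month hazard (0 disables dropout).
    """

    administrative_cutoff: float = math.inf
    dropout_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.administrative_cutoff > 0:
            raise ValueError("administrative cutoff must be > 0")
        if self.dropout_rate < 0:
            raise ValueError("dropout rate must be >= 0")


def _censoring_times(cens: CensoringSpec, n: int, rng: np.random.Generator):
    c = np.full(n, cens.administrative_cutoff)
    if cens.dropout_rate > 0:
        c = np.minimum(c, rng.exponential(1.0 / cens.dropout_rate, size=n))
    return c


def simulate_ipd(
    model: ParametricSurvival,
    n: int,
    cens: CensoringSpec = CensoringSpec(),
    seed: int = 0,
    arm: str = "combo",
    endpoint: str = "OS",
) -> pd.DataFrame:
    """Draw ``n`` right-censored subjects from ``model``.

    Event times come from the inverse CDF applied to uniforms; the observed
    time is ``min(event, censoring)`` with the event flag set accordingly.
    Bit-for-bit reproducible for a given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    u = rng.uniform(size=n)
    t_event = np.maximum(model.quantile(u), 1e-9)
    t_cens = _censoring_times(cens, n, rng)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    return pd.DataFrame(
        {
            "id": np.arange(n),
            "time_months": time,
            "event": event,
            "arm": arm,
            "endpoint": endpoint,
        }
    )


def trial_fixture(
    seed: int = 0,
    cens: CensoringSpec = CensoringSpec(administrative_cutoff=42.0, dropout_rate=0.005),
    n_combo: int = N_COMBO,
    n_control: int = N_CONTROL,
) -> pd.DataFrame:
    """A full two-arm, two-endpoint pseudo-trial (OS and PFS per subject).

    For each subject OS is drawn from the arm's OS model, then PFS from the
    arm's PFS marginal truncated at the subject's OS (inverse-CDF on
    ``u * F_PFS(OS)``), which preserves the PFS marginal approximately while
    enforcing PFS <= OS.  Both endpoints share the subject's censoring time.
    """
    rng = np.random.default_rng(seed)
    frames = []
    for arm, n in (("combo", n_combo), ("control", n_control)):
        os_model = TRIAL_MODELS[arm]["OS"]
        pfs_model = TRIAL_MODELS[arm]["PFS"]
        t_os = np.maximum(os_model.quantile(rng.uniform(size=n)), 1e-9)
        # truncated draw: F_PFS(t) uniform on (0, F_PFS(OS))
        cap = 1.0 - pfs_model.survival(t_os)
        u = rng.uniform(size=n) * cap
        t_pfs = np.minimum(np.maximum(pfs_model.quantile(u), 1e-9), t_os)
        t_c = _censoring_times(cens, n, rng)
        for endpoint, t in (("OS", t_os), ("PFS", t_pfs)):
            time = np.minimum(t, t_c)
            event = (t <= t_c).astype(int)
            frames.append(
                pd.DataFrame(
                    {
                        "id": np.arange(n),
                        "time_months": time,
                        "event": event,
                        "arm": arm,
                        "endpoint": endpoint,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def km_estimate(ipd: pd.DataFrame) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate.

    Returns a DataFrame with columns ``time`` (event/censoring times,
    ascending), ``survival`` (right-continuous step values) and ``at_risk``.
    """
    if len(ipd) == 0:
        raise ValueError("need at least one record for a KM estimate")
    from lifelines import KaplanMeierFitter

    kmf = KaplanMeierFitter()
    kmf.fit(ipd["time_months"], event_observed=ipd["event"])
    table = kmf.event_table
    surv = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": surv.index.to_numpy(dtype=float),
            "survival": surv.to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=float),
        }
    )
    return out


def write_ipd_csv(ipd: pd.DataFrame, path) -> None:
    """Write pseudo-IPD in the canonical CSV dialect (id,time_months,event,arm,endpoint)."""
    ipd.loc[:, IPD_COLUMNS].to_csv(path, index=False)


def read_ipd_csv(path) -> pd.DataFrame:
    ipd = pd.read_csv(path)
    missing = set(IPD_COLUMNS) - set(ipd.columns)
    if missing:
        raise ValueError(f"IPD file missing columns: {sorted(missing)}")
    return ipd
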