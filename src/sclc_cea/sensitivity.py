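"""Uncertainty analyses: one-way (tornado), probabilistic (CEAC), price threshold.

One-way sensitivity varies each scalar parameter to the ends of its range
(+/-20% of baseline unless the config lists an explicit range, as for the
discount rate) with everything else at baseline, recording the ICER swing.

Probabilistic sensitivity redraws all cost parameters from gamma and all
bounded parameters (utilities, incidences, disutilities, proportions) from
beta distributions moment-matched to (baseline, (high - low)/3.92), treating
the range as a 95% interval.  Fitted survival parameters are not resampled:
no variance-covariance information accompanies the published fits.  The
cost-effectiveness acceptability curve is the fraction of draws with
positive incremental net monetary benefit across a willingness-to-pay grid.

The price threshold bisects the intervention drug's per-cycle (1,200 mg)
price until the ICER meets the willingness-to-pay threshold within $1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import RunConfig
from .outcomes import DOMINANT, CEAResult
from .pipeline import run_base_case

__all__ = [
    "ParamRange",
    "TornadoEntry",
    "PSAResult",
    "PriceThreshold",
    "build_ranges",
    "owsa",
    "draw_psa_params",
    "psa",
    "price_threshold",
]

logger = logging.getLogger(__name__)

CEAC_GRID = np.arange(0.0, 300_001.0, 1_000.0)


@dataclass(frozen=True)
class ParamRange:
    name: str
    baseline: float
    low: float
    high: float
    psa_family: str  # 'gamma' | 'beta' | 'fixed'

    def __post_init__(self) -> None:
        if not self.low <= self.baseline <= self.high:
            raise ValueError(f"{self.name}: need low <= baseline <= high")
        if self.psa_family == "beta" and not (0 <= self.low and self.high <= 1):
            raise ValueError(f"{self.name}: beta requires values in [0, 1]")


def build_ranges(config: RunConfig) -> list[ParamRange]:
    """Default ranges for every scalar parameter of a configuration."""
    out = []
    for name in config.param_names():
        lo, hi = config.owsa_range(name)
        out.append(
            ParamRange(
                name=name,
                baseline=config.get_param(name),
                low=lo,
                high=hi,
                psa_family=config.param_kind(name),
            )
        )
    return out


@dataclass(frozen=True)
class TornadoEntry:
    name: str
    icer_low: float
    icer_high: float
    error: str | None = None

    @property
    def swing(self) -> float:
        if self.error:
            return float("nan")
        return abs(self.icer_high - self.icer_low)


def _numeric_icer(result: CEAResult) -> float:
    """ICER as a number for ranking; dominance maps to signed infinity."""
    if isinstance(result.icer, str):
        return -np.inf if result.icer == DOMINANT else np.inf
    return float(result.icer)


def owsa(config: RunConfig, ranges: list[ParamRange] | None = None) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low/high, sorted by swing."""
    if ranges is None:
        ranges = build_ranges(config)
    entries = []
    for rng in ranges:
        try:
            lo = _numeric_icer(run_base_case(config.with_params({rng.name: rng.low})))
            hi = _numeric_icer(run_base_case(config.with_params({rng.name: rng.high})))
            entries.append(TornadoEntry(rng.name, lo, hi))
        except Exception as exc:  # flagged, not dropped
            logger.warning("OWSA failed for %s: %s", rng.name, exc)
            entries.append(TornadoEntry(rng.name, np.nan, np.nan, error=str(exc)))
    df = pd.DataFrame(
        {
            "parameter": [e.name for e in entries],
            "icer_low": [e.icer_low for e in entries],
            "icer_high": [e.icer_high for e in entries],
            "swing": [e.swing for e in entries],
            "error": [e.error for e in entries],
        }
    )
    return df.sort_values("swing", ascending=False, ignore_index=True)


def draw_psa_params(
    ranges: list[ParamRange], seed: int, n: int = 1
) -> dict[str, np.ndarray]:
    """``n`` joint parameter draws; independent across parameters.

    Gamma and beta distributions are moment-matched to mean = baseline and
    sd = (high - low) / 3.92.  Degenerate ranges (sd = 0), 'fixed' entries
    and boundary baselines pass the baseline through.  A beta sd too large
    for its mean is shrunk to feasibility (logged).
    """
    rng = np.random.default_rng(seed)
    out: dict[str, np.ndarray] = {}
    for pr in ranges:
        m = pr.baseline
        sd = (pr.high - pr.low) / 3.92
        if pr.psa_family == "fixed" or sd == 0 or m == 0:
            out[pr.name] = np.full(n, m)
        elif pr.psa_family == "gamma":
            shape = (m / sd) ** 2
            out[pr.name] = rng.gamma(shape, m / shape, size=n)
        elif pr.psa_family == "beta":
            if m >= 1.0:
                out[pr.name] = np.full(n, m)
                continue
            cap = np.sqrt(m * (1 - m))
            if sd >= cap:
                logger.info("shrinking infeasible beta sd for %s", pr.name)
                sd = 0.95 * cap
            nu = m * (1 - m) / sd**2 - 1.0
            out[pr.name] = rng.beta(m * nu, (1 - m) * nu, size=n)
        else:  # pragma: no cover
            raise ValueError(pr.psa_family)
    return out


@dataclass(frozen=True)
class PSAResult:
    n_iter: int
    seed: int
    wtp: float
    delta_cost: np.ndarray = field(repr=False)
    delta_qaly: np.ndarray = field(repr=False)
    ceac: pd.DataFrame = field(repr=False)
    p_ce_at_wtp: float

    def cloud(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "draw": np.arange(self.n_iter),
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "inmb": self.delta_qaly * self.wtp - self.delta_cost,
            }
        )


def psa(
    config: RunConfig,
    n_iter: int = 10_000,
    seed: int = 0,
    ranges: list[ParamRange] | None = None,
    ceac_grid: np.ndarray = CEAC_GRID,
) -> PSAResult:
    """Monte-Carlo uncertainty propagation with CEAC.

    The cohort traces are fixed across draws (survival parameters are not
    resampled), so each draw re-prices and re-weights the same occupancy.
    """
    from .pipeline import cohort_trace  # local import to keep module load light

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    if ranges is None:
        ranges = build_ranges(config)
    draws = draw_psa_params(ranges, seed=seed, n=n_iter)
    traces = {arm: cohort_trace(config, arm) for arm in ("combo", "control")}

    from .costing import accumulate

    d_cost = np.empty(n_iter)
    d_qaly = np.empty(n_iter)
    for i in range(n_iter):
        cfg = config.with_params({name: vals[i] for name, vals in draws.items()})
        inputs = cfg.cost_utility_inputs()
        combo = accumulate(traces["combo"], cfg.arm_spec("combo"), inputs)
        control = accumulate(traces["control"], cfg.arm_spec("control"), inputs)
        d_cost[i] = combo.total_cost - control.total_cost
        d_qaly[i] = combo.total_qaly - control.total_qaly

    nmb = d_qaly[:, None] * ceac_grid[None, :] - d_cost[:, None]
    prob = (nmb > 0).mean(axis=0)
    ceac = pd.DataFrame({"wtp": ceac_grid, "probability": prob})
    p_at = float(((d_qaly * config.wtp - d_cost) > 0).mean())
    return PSAResult(
        n_iter=n_iter,
        seed=seed,
        wtp=config.wtp,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        ceac=ceac,
        p_ce_at_wtp=p_at,
    )


@dataclass(frozen=True)
class PriceThreshold:
    price_per_1200mg: float
    price_per_600mg: float
    icer_at_price: float
    wtp: float
    converged: bool
    n_evaluations: int


def price_threshold(
    config: RunConfig,
    wtp: float | None = None,
    grid: tuple[float, float] | None = None,
    tol_icer: float = 1.0,
    max_iter: int = 200,
) -> PriceThreshold:
    """Bisection for the drug price at which ICER equals willingness-to-pay.

    The varied price is the per-cycle (1,200 mg) acquisition cost of the
    drug named in the config's ``price_simulation`` block.  If the strategy
    is cost-effective across the whole grid the top of the grid is returned
    with ``converged=False`` (and symmetrically for the bottom).
    """
    sim = config.data.get("price_simulation", {})
    drug = sim.get("drug", "benmelstobart")
    if wtp is None:
        wtp = config.wtp
    if grid is None:
        grid = tuple(sim.get("grid_per_1200mg", (0.0, 8000.0)))
    lo, hi = float(grid[0]), float(grid[1])
    param = f"cost.{drug}"
    evals = 0

    def icer_at(price: float) -> float:
        nonlocal evals
        evals += 1
        return _numeric_icer(run_base_case(config.with_params({param: price})))

    f_lo, f_hi = icer_at(lo), icer_at(hi)
    if f_hi <= wtp:  # cost-effective even at the top of the grid
        return PriceThreshold(hi, hi / 2.0, f_hi, wtp, False, evals)
    if f_lo >= wtp:  # not cost-effective even free
        return PriceThreshold(lo, lo / 2.0, f_lo, wtp, False, evals)
    a, b = lo, hi
    mid, f_mid = a, f_lo
    for _ in range(max_iter):
        mid = (a + b) / 2.0
        f_mid = icer_at(mid)
        if abs(f_mid - wtp) < tol_icer:
            break
        if f_mid < wtp:
            a = mid
        else:
            b = mid
    else:  # pragma: no cover - bisection on a monotone ICER always terminates
        logger.warning("price threshold bisection hit max_iter")
    return PriceThreshold(mid, mid / 2.0, f_mid, wtp, abs(f_mid - wtp) < tol_icer, evals)
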