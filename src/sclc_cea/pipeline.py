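"""End-to-end orchestration: base case, sensitivity analyses, report bundle."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from .config import RunConfig, load_config
from .costing import accumulate
from .markov import CohortTrace, occupancy, transition_table
from .outcomes import CEAResult, compare

__all__ = ["cohort_trace", "arm_outcome", "run_base_case", "run_full"]

logger = logging.getLogger(__name__)


def cohort_trace(config: RunConfig, arm: str) -> CohortTrace:
    """Partitioned-survival trace for one arm under the config's cycle plan."""
    return occupancy(
        config.survival_model(arm, "os"),
        config.survival_model(arm, "pfs"),
        config.plan(),
    )


def arm_outcome(config: RunConfig, arm: str):
    trace = cohort_trace(config, arm)
    return accumulate(trace, config.arm_spec(arm), config.cost_utility_inputs())


def run_base_case(config) -> CEAResult:
    """Deterministic base case: both arms, incremental statistics at the WTP."""
    config = load_config(config)
    return compare(
        arm_outcome(config, "combo"), arm_outcome(config, "control"), config.wtp
    )


def _fit_report_on_fixture(seed: int):
    """AIC/BIC ranking of all families on a synthetic trial, per arm/endpoint."""
    import pandas as pd

    from .survival import fit_report
    from .synth import trial_fixture

    ipd = trial_fixture(seed=seed)
    frames = []
    for (arm, endpoint), grp in ipd.groupby(["arm", "endpoint"]):
        rep = fit_report(grp).loc[:, ["aic", "bic"]]
        rep.columns = pd.MultiIndex.from_product([[f"{arm}_{endpoint}"], rep.columns])
        frames.append(rep)
    return pd.concat(frames, axis=1)


def run_full(
    config,
    out_dir,
    seed: int = 0,
    psa_iters: int = 10_000,
    do_owsa: bool = True,
    do_price_sim: bool = True,
    do_fit_report: bool = True,
    price_curve_points: int = 33,
) -> dict:
    """Run every analysis stage and write the report bundle under ``out_dir``.

    Stages are independent where possible: a failure is logged and recorded
    in the summary, and the remaining stages still run.  Returns the summary
    dictionary (also written as ``summary.json``).
    """
    from . import sensitivity as sens

    config = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {
        "perspective": config.perspective,
        "wtp": config.wtp,
        "seed": seed,
        "icer": None,
        "inhb": None,
        "inmb": None,
        "p_ce_at_wtp": None,
        "price_threshold_600mg": None,
        "errors": {},
    }

    # base case + traces
    try:
        result = run_base_case(config)
        result.to_frame().to_csv(out / "base_case.csv", index=False)
        for arm in ("combo", "control"):
            trace = cohort_trace(config, arm)
            trace.to_frame().to_csv(out / f"trace_{arm}.csv", index=False)
            transition_table(
                config.survival_model(arm, "os"),
                config.survival_model(arm, "pfs"),
                config.plan(),
            ).to_csv(out / f"transition_probabilities_{arm}.csv", index=False)
        summary["icer"] = result.icer if isinstance(result.icer, str) else float(result.icer)
        summary["inhb"] = float(result.inhb)
        summary["inmb"] = float(result.inmb)
        summary["delta_cost"] = float(result.delta_cost)
        summary["delta_qaly"] = float(result.delta_qaly)
        summary["cost_effective"] = bool(result.cost_effective)
    except Exception as exc:
        logger.exception("base case failed")
        summary["errors"]["base_case"] = str(exc)

    if do_owsa:
        try:
            tornado = sens.owsa(config)
            tornado.to_csv(out / "tornado.csv", index=False)
            summary["owsa_top_parameters"] = tornado["parameter"].head(5).tolist()
        except Exception as exc:
            logger.exception("OWSA failed")
            summary["errors"]["owsa"] = str(exc)

    if psa_iters and psa_iters > 0:
        try:
            res = sens.psa(config, n_iter=psa_iters, seed=seed)
            res.cloud().to_csv(out / "psa_cloud.csv", index=False)
            res.ceac.to_csv(out / "ceac.csv", index=False)
            summary["p_ce_at_wtp"] = res.p_ce_at_wtp
        except Exception as exc:
            logger.exception("PSA failed")
            summary["errors"]["psa"] = str(exc)

    if do_price_sim:
        try:
            thr = sens.price_threshold(config)
            summary["price_threshold_600mg"] = thr.price_per_600mg
            summary["price_threshold_1200mg"] = thr.price_per_1200mg
            # ICER-vs-price curve across the stated grid
            import pandas as pd

            sim = config.data.get("price_simulation", {})
            lo, hi = sim.get("grid_per_1200mg", (0.0, 8000.0))
            prices = np.linspace(lo, hi, price_curve_points)
            drug = sim.get("drug", "benmelstobart")
            icers = [
                run_base_case(config.with_params({f"cost.{drug}": p})).icer
                for p in prices
            ]
            pd.DataFrame({"price_per_1200mg": prices, "icer": icers}).to_csv(
                out / "price_curve.csv", index=False
            )
        except Exception as exc:
            logger.exception("price simulation failed")
            summary["errors"]["price_simulation"] = str(exc)

    if do_fit_report:
        try:
            _fit_report_on_fixture(seed).to_csv(out / "fit_report.csv")
        except Exception as exc:
            logger.exception("fit report failed")
            summary["errors"]["fit_report"] = str(exc)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2)
    return summary
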