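#!/usr/bin/env python
"""Base-case cost-effectiveness from the China and US perspectives.

Runs the deterministic Markov cohort model for both frozen configurations
and writes the base-case table (per-arm discounted cost, QALYs, life-years,
and the incremental statistics) to results/base_case.csv, plus the cohort
traces and per-category cost breakdowns.
"""

import argparse
from pathlib import Path

import pandas as pd

from sclc_cea.config import RunConfig
from sclc_cea.pipeline import arm_outcome, cohort_trace, run_base_case


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    frames = []
    for name in ("china", "us"):
        cfg = RunConfig.from_name(name)
        res = run_base_case(cfg)
        df = res.to_frame()
        df.insert(0, "perspective", name)
        frames.append(df)
        verdict = "cost-effective" if res.cost_effective else "NOT cost-effective"
        print(f"[{name}] dC={res.delta_cost:,.2f} dE={res.delta_qaly:.4f} "
              f"ICER={res.icer:,.2f}/QALY vs WTP {res.wtp:,.2f} -> {verdict} "
              f"(INHB {res.inhb:.4f}, INMB {res.inmb:,.2f})")
        breakdown = pd.DataFrame(
            {arm: arm_outcome(cfg, arm).breakdown for arm in ("combo", "control")}
        )
        breakdown.to_csv(args.out / f"cost_breakdown_{name}.csv")
        for arm in ("combo", "control"):
            cohort_trace(cfg, arm).to_frame().to_csv(
                args.out / f"trace_{name}_{arm}.csv", index=False
            )
    pd.concat(frames, ignore_index=True).to_csv(args.out / "base_case.csv", index=False)
    print(f"wrote base_case.csv, traces and cost breakdowns under {args.out}/")


if __name__ == "__main__":
    main()
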