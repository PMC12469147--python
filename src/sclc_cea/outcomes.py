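"""Incremental cost-effectiveness statistics.

For arms 1 (intervention) and 0 (comparator) with discounted mean costs and
effects (muC_i, muE_i) and willingness-to-pay threshold lambda:

    ICER      = (muC1 - muC0) / (muE1 - muE0) = dC / dE
    INHB(l)   = dE - dC / l        (QALYs)
    INMB(l)   = dE * l - dC        (currency);  INMB = INHB * l

Dominance is reported as a flag rather than a signed ICER: a negative ratio
mixes "cheaper and better" with "costlier and worse".
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .costing import ArmOutcome

__all__ = ["DOMINANT", "DOMINATED", "UNDEFINED", "icer", "inhb", "inmb",
           "CEAResult", "compare"]

DOMINANT = "dominant"      # dC < 0, dE > 0: intervention saves money and adds QALYs
DOMINATED = "dominated"    # dC > 0, dE < 0
UNDEFINED = "undefined"    # dE == 0


def icer(delta_cost: float, delta_qaly: float) -> float | str:
    """dC / dE, or a dominance flag where the ratio is not meaningful."""
    if delta_qaly == 0:
        return UNDEFINED
    if delta_qaly > 0 and delta_cost < 0:
        return DOMINANT
    if delta_qaly < 0 and delta_cost > 0:
        return DOMINATED
    return delta_cost / delta_qaly


def inhb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net health benefit dE - dC/lambda, in QALYs."""
    if wtp <= 0:
        raise ValueError("WTP must be > 0")
    return delta_qaly - delta_cost / wtp


def inmb(delta_cost: float, delta_qaly: float, wtp: float) -> float:
    """Incremental net monetary benefit dE*lambda - dC, in currency."""
    if wtp <= 0:
        raise ValueError("WTP must be > 0")
    return delta_qaly * wtp - delta_cost


@dataclass(frozen=True)
class CEAResult:
    """Two-arm comparison at a willingness-to-pay threshold."""

    intervention: ArmOutcome
    comparator: ArmOutcome
    wtp: float
    delta_cost: float
    delta_qaly: float
    delta_ly: float
    icer: float | str
    inhb: float
    inmb: float
    cost_effective: bool

    def to_frame(self) -> pd.DataFrame:
        """Base-case table: one row per arm plus the incremental columns."""
        rows = [
            {
                "arm": self.intervention.arm,
                "cost": self.intervention.total_cost,
                "qaly": self.intervention.total_qaly,
                "ly": self.intervention.total_ly,
                "delta_cost": self.delta_cost,
                "delta_qaly": self.delta_qaly,
                "inhb": self.inhb,
                "inmb": self.inmb,
                "icer": self.icer,
            },
            {
                "arm": self.comparator.arm,
                "cost": self.comparator.total_cost,
                "qaly": self.comparator.total_qaly,
                "ly": self.comparator.total_ly,
            },
        ]
        return pd.DataFrame(rows)


def compare(intervention: ArmOutcome, comparator: ArmOutcome, wtp: float) -> CEAResult:
    """Populate all incremental statistics for intervention vs comparator."""
    d_cost = intervention.total_cost - comparator.total_cost
    d_qaly = intervention.total_qaly - comparator.total_qaly
    d_ly = intervention.total_ly - comparator.total_ly
    nmb = inmb(d_cost, d_qaly, wtp)
    return CEAResult(
        intervention=intervention,
        comparator=comparator,
        wtp=wtp,
        delta_cost=d_cost,
        delta_qaly=d_qaly,
        delta_ly=d_ly,
        icer=icer(d_cost, d_qaly),
        inhb=inhb(d_cost, d_qaly, wtp),
        inmb=nmb,
        cost_effective=nmb > 0,
    )
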