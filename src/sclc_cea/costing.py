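"""Cost and QALY accrual over a cohort trace.

Cost categories follow the structure of the published input tables: drug
acquisition per 21-day cycle, intravenous administration, routine monitoring
(laboratory panel every cycle, PET-CT every second cycle), best supportive
care, grade >=3 adverse events (charged once, in the first cycle), a
proportion-weighted second-line (topotecan) regimen at or after progression,
and a one-time end-of-life cost at death.  Utilities attach to the PFS and
PD states; adverse events subtract a one-time QALY loss.

Which states the monitoring / supportive-care categories span, and for how
many cycles the maintenance drugs are actually paid, are perspective
configuration (see the bundled configs and the methods note): the Chinese
healthcare-system perspective includes all healthcare-related expenses and
caps patient drug payments via assistance programs, the US payer perspective
includes direct medical costs only and pays to progression.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .markov import CohortTrace

__all__ = [
    "AdverseEvent",
    "ArmSpec",
    "CostUtilityInputs",
    "ArmOutcome",
    "carboplatin_dose",
    "bsa_dose",
    "cycle_cost",
    "event_costs",
    "accumulate",
]


def carboplatin_dose(target_auc: float, gfr: float) -> float:
    """Calvert formula: dose (mg) = AUC x (GFR + 25)."""
    if target_auc <= 0 or gfr < 0:
        raise ValueError("AUC must be > 0 and GFR >= 0")
    return target_auc * (gfr + 25.0)


def bsa_dose(dose_per_m2: float, bsa: float) -> float:
    """Body-surface-area dosing: mg per administration day."""
    if dose_per_m2 < 0 or bsa <= 0:
        raise ValueError("dose must be >= 0 and BSA > 0")
    return dose_per_m2 * bsa


@dataclass(frozen=True)
class AdverseEvent:
    """One grade >=3 adverse event: incidence, management cost, disutility."""

    name: str
    incidence: float
    cost: float
    disutility: float

    def __post_init__(self) -> None:
        if not 0 <= self.incidence <= 1:
            raise ValueError(f"incidence of {self.name} must be in [0, 1]")
        if self.cost < 0 or self.disutility < 0:
            raise ValueError(f"cost/disutility of {self.name} must be >= 0")


@dataclass(frozen=True)
class ArmSpec:
    """One strategy: drugs, payment schedule, adverse-event profile."""

    name: str
    on_pfs_drugs: tuple[tuple[str, float], ...] = ()
    chemo_drugs: tuple[tuple[str, float], ...] = ()
    chemo_cycles: int = 4
    paid_treatment_cycles: int | None = None  # None: paid while in PFS
    admin_cost_per_iv_cycle: float = 0.0
    admin_scope: str = "chemo"  # 'pfs': every cycle in PFS; 'chemo': chemo cycles only
    subsequent_treatment_proportion: float = 0.0
    subsequent_regimen_cost: float = 0.0  # per cycle of the second-line drug
    ae_profile: tuple[AdverseEvent, ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.subsequent_treatment_proportion <= 1:
            raise ValueError("subsequent treatment proportion must be in [0, 1]")
        if self.chemo_cycles < 0:
            raise ValueError("chemo_cycles must be >= 0")
        if any(c < 0 for _, c in self.on_pfs_drugs + self.chemo_drugs):
            raise ValueError("drug costs must be >= 0")
        if self.admin_scope not in ("pfs", "chemo"):
            raise ValueError("admin_scope must be 'pfs' or 'chemo'")

    @property
    def on_pfs_cost(self) -> float:
        return sum(c for _, c in self.on_pfs_drugs)

    @property
    def chemo_cost(self) -> float:
        return sum(c for _, c in self.chemo_drugs)

    @property
    def ae_cost(self) -> float:
        return sum(ae.incidence * ae.cost for ae in self.ae_profile)

    @property
    def ae_disutility(self) -> float:
        return sum(ae.incidence * ae.disutility for ae in self.ae_profile)


@dataclass(frozen=True)
class CostUtilityInputs:
    """State utilities, downstream-care unit costs and category scopes."""

    u_pfs: float
    u_pd: float
    bsc_per_cycle: float
    eol_onetime: float
    lab_per_cycle: float = 0.0
    pet_ct_cost: float = 0.0
    pet_every_n_cycles: int = 2
    monitoring_scope: str = "pfs"  # lab test: 'pfs' or 'alive'
    pet_scope: str = "pfs"
    bsc_scope: str = "pd"  # 'pd' or 'alive'
    subsequent_mode: str = "one_time"  # or 'per_cycle'
    subsequent_cycles: int = 4
    ae_disutility_cycles: float = 1.0
    perspective: str = "china"
    wtp: float = 38042.49

    def __post_init__(self) -> None:
        if not (0 <= self.u_pfs <= 1 and 0 <= self.u_pd <= 1):
            raise ValueError("utilities must be in [0, 1]")
        if self.u_pd > self.u_pfs:
            # sensitivity ranges legitimately cross (the published PFS-utility
            # range dips below the PD baseline); warn rather than refuse
            warnings.warn("u_pd exceeds u_pfs", stacklevel=2)
        for name in ("bsc_per_cycle", "eol_onetime", "lab_per_cycle", "pet_ct_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.monitoring_scope not in ("pfs", "alive") or self.pet_scope not in ("pfs", "alive"):
            raise ValueError("monitoring/pet scope must be 'pfs' or 'alive'")
        if self.bsc_scope not in ("pd", "alive"):
            raise ValueError("bsc_scope must be 'pd' or 'alive'")
        if self.subsequent_mode not in ("one_time", "per_cycle"):
            raise ValueError("subsequent_mode must be 'one_time' or 'per_cycle'")
        if not self.wtp > 0:
            raise ValueError("WTP must be > 0")


@dataclass(frozen=True)
class ArmOutcome:
    """Discounted totals for one arm, with a per-category cost breakdown."""

    arm: str
    total_cost: float
    total_qaly: float
    total_ly: float
    breakdown: dict[str, float] = field(default_factory=dict)


def _is_pet_cycle(k, every: int) -> np.ndarray:
    """PET-CT cycles: every ``every``-th cycle, first scan after ``every`` cycles."""
    return (np.asarray(k) % every) == (every - 1)


def cycle_cost(arm: ArmSpec, inputs: CostUtilityInputs, k: int, state: str) -> float:
    """Per-member cost of occupying ``state`` during cycle ``k`` (undiscounted).

    One-time flows (adverse events, end of life, one-time subsequent
    treatment) are charged separately -- see :func:`event_costs` and
    :func:`accumulate`.
    """
    if k < 0:
        raise ValueError("cycle index must be >= 0")
    pet = inputs.pet_ct_cost if _is_pet_cycle(k, inputs.pet_every_n_cycles) else 0.0
    if state == "pfs":
        cost = 0.0
        paid = arm.paid_treatment_cycles
        if paid is None or k < paid:
            cost += arm.on_pfs_cost
        if k < arm.chemo_cycles:
            cost += arm.chemo_cost
        if arm.admin_scope == "pfs" or k < arm.chemo_cycles:
            cost += arm.admin_cost_per_iv_cycle
        cost += inputs.lab_per_cycle + pet
        if inputs.bsc_scope == "alive":
            cost += inputs.bsc_per_cycle
        return cost
    if state == "pd":
        cost = inputs.bsc_per_cycle
        if inputs.monitoring_scope == "alive":
            cost += inputs.lab_per_cycle
        if inputs.pet_scope == "alive":
            cost += pet
        if inputs.subsequent_mode == "per_cycle":
            cost += arm.subsequent_treatment_proportion * arm.subsequent_regimen_cost
        return cost
    raise ValueError(f"unknown state {state!r}; expected 'pfs' or 'pd'")


def event_costs(trace: CohortTrace, arm: ArmSpec, inputs: CostUtilityInputs) -> dict[str, float]:
    """Discounted one-time flows: subsequent treatment at PD entry, end of life at death."""
    disc = trace.discount()
    out = {"end_of_life": float(inputs.eol_onetime * np.sum(trace.new_dead * disc))}
    if inputs.subsequent_mode == "one_time":
        course = arm.subsequent_regimen_cost * inputs.subsequent_cycles
        out["subsequent_treatment"] = float(
            arm.subsequent_treatment_proportion * course * np.sum(trace.new_pd * disc)
        )
    else:
        out["subsequent_treatment"] = 0.0
    return out


def accumulate(trace: CohortTrace, arm: ArmSpec, inputs: CostUtilityInputs) -> ArmOutcome:
    """Discounted totals for one arm over the full trace.

    Costs are occupancy-weighted per-cycle amounts plus the one-time flows;
    QALYs are utility-weighted person-time minus the one-time adverse-event
    loss (disutility x incidence over ``ae_disutility_cycles`` cycles,
    charged at model start); life-years use utilities of 1 and no loss.
    """
    plan = trace.plan
    cp, cq = trace.state_credit()
    disc = trace.discount()
    k = np.arange(plan.n_cycles)
    dty = plan.cycle_length_years

    pfs_pt = cp * disc  # discounted person-time weights per cycle
    pd_pt = cq * disc
    alive_pt = pfs_pt + pd_pt

    paid = arm.paid_treatment_cycles
    paid_mask = np.ones_like(k, dtype=bool) if paid is None else (k < paid)
    chemo_mask = k < arm.chemo_cycles
    admin_mask = np.ones_like(k, dtype=bool) if arm.admin_scope == "pfs" else chemo_mask
    pet_mask = _is_pet_cycle(k, inputs.pet_every_n_cycles)

    br: dict[str, float] = {}
    br["treatment_drugs"] = arm.on_pfs_cost * float(pfs_pt[paid_mask].sum())
    br["chemotherapy"] = arm.chemo_cost * float(pfs_pt[chemo_mask].sum())
    br["administration"] = arm.admin_cost_per_iv_cycle * float(pfs_pt[admin_mask].sum())
    lab_pt = alive_pt if inputs.monitoring_scope == "alive" else pfs_pt
    pet_pt = alive_pt if inputs.pet_scope == "alive" else pfs_pt
    br["monitoring"] = inputs.lab_per_cycle * float(lab_pt.sum()) + inputs.pet_ct_cost * float(
        pet_pt[pet_mask].sum()
    )
    bsc_pt = alive_pt if inputs.bsc_scope == "alive" else pd_pt
    br["best_supportive_care"] = inputs.bsc_per_cycle * float(bsc_pt.sum())
    br["adverse_events"] = arm.ae_cost  # charged once at model start (t = 0)
    if inputs.subsequent_mode == "per_cycle":
        br["subsequent_treatment"] = (
            arm.subsequent_treatment_proportion * arm.subsequent_regimen_cost * float(pd_pt.sum())
        )
        br["end_of_life"] = event_costs(trace, arm, inputs)["end_of_life"]
    else:
        br.update(event_costs(trace, arm, inputs))

    total_cost = float(sum(br.values()))
    ae_qaly_loss = arm.ae_disutility * inputs.ae_disutility_cycles * dty
    total_qaly = float(
        ((cp * inputs.u_pfs + cq * inputs.u_pd) * disc).sum() * dty - ae_qaly_loss
    )
    total_ly = float(alive_pt.sum() * dty)
    return ArmOutcome(
        arm=arm.name,
        total_cost=total_cost,
        total_qaly=total_qaly,
        total_ly=total_ly,
        breakdown=br,
    )
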