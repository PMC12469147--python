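"""Run configuration: one YAML block per perspective, mirroring the input tables.

Every scalar model input (unit costs, utilities, adverse-event incidences
and disutilities, subsequent-treatment proportions, the discount rate) is
addressable by a dotted name (e.g. ``cost.benmelstobart``,
``ae_incidence.combo.anemia``), which is what the one-way and probabilistic
sensitivity analyses iterate over.  Structural settings (cycle mechanics,
drug schedules, category scopes, survival parameters) are fixed per config.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import yaml

from .costing import AdverseEvent, ArmSpec, CostUtilityInputs
from .markov import CyclePlan
from .survival import ParametricSurvival

__all__ = ["ConfigError", "RunConfig", "load_config", "bundled_config_names"]

ARMS = ("combo", "control")

_REQUIRED_TOP = (
    "perspective", "wtp_per_qaly", "plan", "survival_models", "utilities",
    "unit_costs", "ae", "subsequent_treatment", "care_scopes", "arms",
)


class ConfigError(ValueError):
    """A configuration file is missing or violates the schema."""


@dataclass(frozen=True)
class RunConfig:
    """A fully-resolved model configuration for one perspective."""

    data: dict

    def __post_init__(self) -> None:
        missing = [k for k in _REQUIRED_TOP if k not in self.data]
        if missing:
            raise ConfigError(f"config missing required blocks: {missing}")
        bad = []
        for arm in ARMS:
            if arm not in self.data["arms"]:
                bad.append(f"arms.{arm}")
            if arm not in self.data["subsequent_treatment"]["proportion"]:
                bad.append(f"subsequent_treatment.proportion.{arm}")
        for name, spec in self.data["ae"].items():
            for key in ("cost", "disutility", "incidence"):
                if key not in spec:
                    bad.append(f"ae.{name}.{key}")
        if bad:
            raise ConfigError(f"config fields missing or invalid: {bad}")

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def from_name(cls, name: str) -> "RunConfig":
        """Load one of the bundled perspective configs (e.g. 'china', 'us')."""
        ref = resources.files("sclc_cea.configs") / f"{name}.yaml"
        if not ref.is_file():
            raise ConfigError(
                f"no bundled config {name!r}; available: {bundled_config_names()}"
            )
        return cls(yaml.safe_load(ref.read_text()))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.data, fh, sort_keys=False)

    # -- flat parameter registry ------------------------------------------

    def param_names(self) -> list[str]:
        names = [f"cost.{k}" for k in self.data["unit_costs"]]
        names += ["utility.pfs", "utility.pd"]
        for ae in self.data["ae"]:
            names += [f"ae_cost.{ae}", f"ae_disutility.{ae}"]
            names += [f"ae_incidence.{arm}.{ae}" for arm in ARMS]
        names += [f"subsequent_proportion.{arm}" for arm in ARMS]
        names += ["discount_rate"]
        return names

    def _locate(self, name: str):
        parts = name.split(".")
        d = self.data
        try:
            if parts[0] == "cost":
                return d["unit_costs"], parts[1]
            if parts[0] == "utility":
                return d["utilities"], parts[1]
            if parts[0] == "ae_cost":
                return d["ae"][parts[1]], "cost"
            if parts[0] == "ae_disutility":
                return d["ae"][parts[1]], "disutility"
            if parts[0] == "ae_incidence":
                return d["ae"][parts[2]]["incidence"], parts[1]
            if parts[0] == "subsequent_proportion":
                return d["subsequent_treatment"]["proportion"], parts[1]
            if name == "discount_rate":
                return d["plan"], "discount_rate"
        except KeyError:
            pass
        raise ConfigError(f"unknown parameter {name!r}")

    def get_param(self, name: str) -> float:
        container, key = self._locate(name)
        if key not in container:
            raise ConfigError(f"unknown parameter {name!r}")
        return float(container[key])

    def with_params(self, updates: dict[str, float]) -> "RunConfig":
        """A copy of this config with the named scalar parameters replaced."""
        new = copy.deepcopy(self.data)
        cfg = RunConfig(new)
        for name, value in updates.items():
            container, key = cfg._locate(name)
            if key not in container:
                raise ConfigError(f"unknown parameter {name!r}")
            container[key] = float(value)
        return cfg

    @staticmethod
    def param_kind(name: str) -> str:
        """PSA sampling family: 'gamma' (costs), 'beta' (bounded), 'fixed'."""
        head = name.split(".")[0]
        if head in ("cost", "ae_cost"):
            return "gamma"
        if head in ("utility", "ae_disutility", "ae_incidence", "subsequent_proportion"):
            return "beta"
        return "fixed"  # discount rate: varied in OWSA only

    # -- model builders ----------------------------------------------------

    @property
    def perspective(self) -> str:
        return self.data["perspective"]

    @property
    def wtp(self) -> float:
        return float(self.data["wtp_per_qaly"])

    def plan(self) -> CyclePlan:
        return CyclePlan(**self.data["plan"])

    def survival_model(self, arm: str, endpoint: str) -> ParametricSurvival:
        spec = self.data["survival_models"][arm][endpoint.lower()]
        return ParametricSurvival(spec["family"], dict(spec["params"]))

    def arm_spec(self, arm: str) -> ArmSpec:
        a = self.data["arms"][arm]
        costs = self.data["unit_costs"]
        sub = self.data["subsequent_treatment"]
        profile = tuple(
            AdverseEvent(
                name=name,
                incidence=float(spec["incidence"][arm]),
                cost=float(spec["cost"]),
                disutility=float(spec["disutility"]),
            )
            for name, spec in self.data["ae"].items()
        )
        return ArmSpec(
            name=a.get("label", arm),
            on_pfs_drugs=tuple((d, float(costs[d])) for d in a["maintenance_drugs"]),
            chemo_drugs=tuple((d, float(costs[d])) for d in a["chemo_drugs"]),
            chemo_cycles=int(a["chemo_cycles"]),
            paid_treatment_cycles=a.get("paid_maintenance_cycles"),
            admin_cost_per_iv_cycle=float(costs["administration_per_iv_cycle"]),
            admin_scope=a["admin_scope"],
            subsequent_treatment_proportion=float(sub["proportion"][arm]),
            subsequent_regimen_cost=float(costs[sub["drug"]]),
            ae_profile=profile,
        )

    def cost_utility_inputs(self) -> CostUtilityInputs:
        d = self.data
        scopes = d["care_scopes"]
        return CostUtilityInputs(
            u_pfs=float(d["utilities"]["pfs"]),
            u_pd=float(d["utilities"]["pd"]),
            bsc_per_cycle=float(d["unit_costs"]["best_supportive_care"]),
            eol_onetime=float(d["unit_costs"]["end_of_life"]),
            lab_per_cycle=float(d["unit_costs"]["laboratory_test"]),
            pet_ct_cost=float(d["unit_costs"]["pet_ct"]),
            pet_every_n_cycles=int(d.get("pet_every_n_cycles", 2)),
            monitoring_scope=scopes["monitoring"],
            pet_scope=scopes["pet"],
            bsc_scope=scopes["bsc"],
            subsequent_mode=d["subsequent_treatment"]["mode"],
            subsequent_cycles=int(d["subsequent_treatment"]["cycles"]),
            ae_disutility_cycles=float(d.get("ae_disutility_cycles", 1)),
            perspective=d["perspective"],
            wtp=self.wtp,
        )

    def owsa_range(self, name: str) -> tuple[float, float]:
        """(low, high) for one-way sensitivity: +/-20% unless explicitly listed."""
        owsa = self.data.get("owsa", {})
        explicit = owsa.get("explicit_ranges", {})
        if name in explicit:
            lo, hi = explicit[name]
            return float(lo), float(hi)
        rel = float(owsa.get("relative_range", 0.20))
        base = self.get_param(name)
        lo, hi = base * (1 - rel), base * (1 + rel)
        if self.param_kind(name) == "beta" or name.startswith("utility."):
            hi = min(hi, 1.0)
        return lo, hi


def load_config(source) -> RunConfig:
    """Load a config from a bundled name, a path, or pass through a RunConfig."""
    if isinstance(source, RunConfig):
        return source
    if isinstance(source, (str, Path)) and Path(str(source)).exists():
        return RunConfig.from_yaml(source)
    return RunConfig.from_name(str(source))


def bundled_config_names() -> list[str]:
    root = resources.files("sclc_cea.configs")
    return sorted(p.name[:-5] for p in root.iterdir() if p.name.endswith(".yaml"))
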