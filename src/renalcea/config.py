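"""Model configuration mirroring the published input-parameter table.

The configuration holds everything the simulation needs: the fitted
parametric survival laws per treatment line, adverse-event (AE)
discontinuation and mortality probabilities, unit drug prices and dosing
schedules, administration / AE-management / best-supportive-care (BSC)
costs, per-line utilities, patient characteristics, and the discounting and
horizon settings. It serialises to/from a YAML file whose layout mirrors
the row names of the source table, so the same file that users edit also
drives the sensitivity-analysis machinery.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

from .lifetables import LifeTable, make_life_table
from .survival import ParametricSurvival

__all__ = [
    "ARM_NIVO_CABO",
    "ARM_SUNITINIB",
    "ARMS",
    "ModelConfig",
    "drug_cost_per_cycle",
    "config_from_dict",
    "config_to_dict",
    "load_config",
    "save_config",
    "set_param",
]

ARM_NIVO_CABO = "nivolumab_cabozantinib"
ARM_SUNITINIB = "sunitinib"
ARMS = (ARM_NIVO_CABO, ARM_SUNITINIB)

#: Dosing schedules per 42-day cycle. Intravenous nivolumab is given every
#: two weeks (3 infusions/cycle); oral drugs are priced dose-proportionally
#: from their unit strength (cabozantinib 40 mg daily at a 60 mg unit price;
#: sunitinib 50 mg daily for 4 of 6 weeks; axitinib 5 mg twice daily;
#: sorafenib 400 mg twice daily).
REGIMEN_SCHEDULES: dict[str, dict] = {
    ARM_NIVO_CABO: {
        "iv": [("nivolumab", 3.0)],                     # doses per cycle
        "oral": [("cabozantinib", 40.0 / 60.0, 42.0)],  # (drug, units/day, days)
    },
    ARM_SUNITINIB: {"iv": [], "oral": [("sunitinib", 1.0, 28.0)]},
    "axitinib": {"iv": [], "oral": [("axitinib", 2.0, 42.0)]},
    "sorafenib": {"iv": [], "oral": [("sorafenib", 4.0, 42.0)]},
    "bsc": {"iv": [], "oral": []},
}


def drug_cost_per_cycle(
    regimen: str,
    unit_prices: Mapping[str, float],
    weight_kg: float = 70.0,
    cycle_days: float = 42.0,
) -> float:
    """Drug acquisition cost (USD) for one model cycle of a regimen.

    All listed drugs are flat-priced, so ``weight_kg`` currently does not
    alter the result; it is retained as a hook because the uncertainty
    program varies it. Schedules are defined per 42-day cycle and scale
    proportionally with ``cycle_days``.
    """
    if regimen not in REGIMEN_SCHEDULES:
        raise ValueError(f"unknown regimen {regimen!r}")
    sched = REGIMEN_SCHEDULES[regimen]
    scale = cycle_days / 42.0
    cost = 0.0
    for drug, doses in sched["iv"]:
        cost += doses * scale * unit_prices[drug]
    for drug, units_per_day, days in sched["oral"]:
        cost += units_per_day * days * scale * unit_prices[drug]
    return cost


@dataclass
class ModelConfig:
    """Full base-case configuration of the two-arm sequencing model."""

    # survival laws (time in months)
    pfs: dict[str, ParametricSurvival]
    bsc_os: ParametricSurvival
    # cumulative AE discontinuation / one-time AE mortality / grade>=3 AE
    discontinuation: dict[str, float]
    ae_mortality: dict[str, float]
    ae_grade3plus: dict[str, float]
    # costs (2021 USD)
    unit_prices: dict[str, float]
    ae_management: dict[str, float]
    admin_iv_infusion: float
    bsc_cost_per_cycle: float
    # utilities
    utilities: dict[str, float]
    ae_disutility: float
    # patient & settings
    life_table: LifeTable
    start_age: float = 62.0
    weight_kg: float = 70.0
    cycle_days: float = 42.0
    discount_rate_annual: float = 0.03
    wtp_per_qaly: float = 150_000.0
    age_cap: float = 100.0
    horizon_years: float | None = None
    half_cycle_correction: bool = False
    bsc_switch_prob: dict[str, float] = field(
        default_factory=lambda: {a: 0.0 for a in ARMS}
    )
    # one-way ranges / PSA standard deviations by parameter path
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)
    psa_sd: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.discount_rate_annual < 0:
            raise ValueError("discount rate must be nonnegative")
        if self.age_cap <= self.start_age:
            raise ValueError("age cap must exceed the starting age")
        for d in (self.discontinuation, self.ae_mortality, self.ae_grade3plus):
            for k, v in d.items():
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"probability {k}={v} outside [0, 1]")
        for k, v in self.utilities.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"utility {k}={v} outside [0, 1]")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)

    @property
    def cycle_months(self) -> float:
        return self.cycle_days / 30.4375

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.25

    def n_cycles(self) -> int:
        horizon = self.age_cap - self.start_age
        if self.horizon_years is not None:
            horizon = min(horizon, self.horizon_years)
        return int(np.floor(horizon * 365.25 / self.cycle_days))


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _survival_from_dict(d: Mapping) -> ParametricSurvival:
    if d["family"] == "exponential":
        value = float(d.get("value", d.get("scale")))
        how = d.get("parameterization", "mean")
        if how == "mean":
            return ParametricSurvival.exponential(mean=value)
        if how == "rate":
            return ParametricSurvival.exponential(rate=value)
        raise ValueError(f"unknown exponential parameterization {how!r}")
    return ParametricSurvival(d["family"], float(d["shape"]), float(d["scale"]))


def _survival_to_dict(m: ParametricSurvival) -> dict:
    if m.family == "exponential":
        return {"family": "exponential", "value": m.scale, "parameterization": "mean"}
    return m.to_dict()


def config_from_dict(d: Mapping) -> ModelConfig:
    s = d.get("settings", {})
    lt = d.get("life_table", {"gompertz": {}})
    if "csv" in lt:
        life_table = LifeTable.from_csv(lt["csv"])
    else:
        life_table = make_life_table(**lt.get("gompertz", {}))
    probs = d["probabilities"]
    costs = d["costs"]
    util = dict(d["utilities"])
    ranges = {k: (float(v[0]), float(v[1])) for k, v in d.get("ranges", {}).items()}
    return ModelConfig(
        pfs={k: _survival_from_dict(v) for k, v in d["survival"]["pfs"].items()},
        bsc_os=_survival_from_dict(d["survival"]["bsc_os"]),
        discontinuation=dict(probs["discontinuation_ae"]),
        ae_mortality=dict(probs["ae_mortality"]),
        ae_grade3plus=dict(probs["ae_grade3plus"]),
        unit_prices=dict(costs["unit_prices"]),
        ae_management=dict(costs["ae_management"]),
        admin_iv_infusion=float(costs["admin_iv_infusion"]),
        bsc_cost_per_cycle=float(costs["bsc_per_cycle"]),
        utilities={k: float(v) for k, v in util.items() if k != "ae_disutility"},
        ae_disutility=float(util["ae_disutility"]),
        life_table=life_table,
        start_age=float(s.get("start_age", 62.0)),
        weight_kg=float(s.get("weight_kg", 70.0)),
        cycle_days=float(s.get("cycle_days", 42.0)),
        discount_rate_annual=float(s.get("discount_rate_annual", 0.03)),
        wtp_per_qaly=float(s.get("wtp_per_qaly", 150_000.0)),
        age_cap=float(s.get("age_cap", 100.0)),
        half_cycle_correction=bool(s.get("half_cycle_correction", False)),
        ranges=ranges,
        psa_sd={k: float(v) for k, v in d.get("psa", {}).get("sd", {}).items()},
    )


def config_to_dict(c: ModelConfig) -> dict:
    return {
        "settings": {
            "cycle_days": c.cycle_days,
            "discount_rate_annual": c.discount_rate_annual,
            "wtp_per_qaly": c.wtp_per_qaly,
            "start_age": c.start_age,
            "weight_kg": c.weight_kg,
            "age_cap": c.age_cap,
            "half_cycle_correction": c.half_cycle_correction,
        },
        "survival": {
            "pfs": {k: _survival_to_dict(v) for k, v in c.pfs.items()},
            "bsc_os": _survival_to_dict(c.bsc_os),
        },
        "probabilities": {
            "discontinuation_ae": dict(c.discontinuation),
            "ae_mortality": dict(c.ae_mortality),
            "ae_grade3plus": dict(c.ae_grade3plus),
        },
        "costs": {
            "unit_prices": dict(c.unit_prices),
            "ae_management": dict(c.ae_management),
            "admin_iv_infusion": c.admin_iv_infusion,
            "bsc_per_cycle": c.bsc_cost_per_cycle,
        },
        "utilities": {**c.utilities, "ae_disutility": c.ae_disutility},
        "life_table": {"gompertz": dict(c.life_table.gompertz or {})}
        if c.life_table.gompertz
        else {"table": "external"},
        "ranges": {k: list(v) for k, v in c.ranges.items()},
        "psa": {"sd": dict(c.psa_sd)},
    }


def load_config(path) -> ModelConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Parameter addressing (used by the uncertainty program)
# ---------------------------------------------------------------------------

_SCALAR_PARAMS = {
    "admin_iv_infusion": "admin_iv_infusion",
    "bsc_cost": "bsc_cost_per_cycle",
    "ae_disutility": "ae_disutility",
    "start_age": "start_age",
    "weight_kg": "weight_kg",
}
_DICT_PARAMS = {
    "unit_price": "unit_prices",
    "ae_management": "ae_management",
    "utility": "utilities",
    "discontinuation": "discontinuation",
    "ae_mortality": "ae_mortality",
    "ae_grade3plus": "ae_grade3plus",
}


def set_param(config: ModelConfig, name: str, value: float) -> ModelConfig:
    """Return a copy of ``config`` with one named parameter replaced.

    Names follow ``"group.key"`` paths mirroring the input table, e.g.
    ``"unit_price.nivolumab"``, ``"utility.first_line"``,
    ``"discontinuation.axitinib"``, or scalars such as ``"start_age"``.
    """
    out = config.copy()
    if name in _SCALAR_PARAMS:
        setattr(out, _SCALAR_PARAMS[name], float(value))
        return out
    if "." in name:
        group, key = name.split(".", 1)
        if group in _DICT_PARAMS:
            d = getattr(out, _DICT_PARAMS[group])
            if key not in d:
                raise KeyError(f"unknown parameter {name!r}")
            d[key] = float(value)
            return out
    raise KeyError(f"unknown parameter {name!r}")


def get_param(config: ModelConfig, name: str) -> float:
    if name in _SCALAR_PARAMS:
        return float(getattr(config, _SCALAR_PARAMS[name]))
    if "." in name:
        group, key = name.split(".", 1)
        if group in _DICT_PARAMS:
            return float(getattr(config, _DICT_PARAMS[group])[key])
    raise KeyError(f"unknown parameter {name!r}")
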