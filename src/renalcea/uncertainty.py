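"""One-way, probabilistic and scenario sensitivity analyses.

The uncertainty program mirrors standard cost-effectiveness practice:

* **one-way (tornado)** — each parameter moves to its low and high bound
  with everything else at base; runs share common random numbers so the
  span reflects the parameter, not sampling noise;
* **probabilistic (PSA)** — all parameters are jointly redrawn each
  iteration (gamma for costs, beta for probabilities and utilities, normal
  for starting age and weight), a fresh cohort is simulated, and the
  incremental outcomes are recorded;
* **scenarios** — price fractions for a drug or a whole strategy, truncated
  time horizons, and direct-to-BSC switching after first-line progression.

Distribution hyperparameters are moment-matched from the printed mean and
either a printed SD or a range treated as a 95% interval
(``SD = range / (2 * 1.96)``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ARMS, ModelConfig, get_param, set_param
from .economics import IncrementalResult, icer
from .microsim import run_cohort

__all__ = [
    "ParamSpec",
    "default_param_specs",
    "sample_param",
    "one_way",
    "psa",
    "scenario_price",
    "scenario_horizon",
    "scenario_bsc_switch",
]

_COST_RANGE_FRACTION = 0.20  # costs varied +/-20% from baseline
_Z95 = 1.959963984540054


@dataclass(frozen=True)
class ParamSpec:
    """One uncertain parameter: base value, range and PSA distribution."""

    name: str
    base: float
    low: float
    high: float
    distribution: str  # gamma | beta | normal | fixed
    sd: float | None = None

    def __post_init__(self) -> None:
        if not self.low <= self.base <= self.high:
            raise ValueError(f"{self.name}: need low <= base <= high")
        if self.distribution not in ("gamma", "beta", "normal", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution")

    @property
    def sd_effective(self) -> float:
        if self.sd is not None:
            return self.sd
        return (self.high - self.low) / (2.0 * _Z95)


def default_param_specs(config: ModelConfig) -> list[ParamSpec]:
    """Build the uncertain-parameter list from the configuration.

    Costs get gamma distributions with a +/-20% range; utilities and
    probabilities get beta distributions (ranges as printed where the
    source table prints them, otherwise +/-20%); starting age and weight
    are normal. Structural survival parameters stay fixed.
    """
    specs: list[ParamSpec] = []

    def rng_for(name: str, base: float, frac: float = _COST_RANGE_FRACTION):
        if name in config.ranges:
            return config.ranges[name]
        return base * (1 - frac), base * (1 + frac)

    for drug in config.unit_prices:
        name = f"unit_price.{drug}"
        lo, hi = rng_for(name, config.unit_prices[drug])
        specs.append(ParamSpec(name, config.unit_prices[drug], lo, hi, "gamma"))
    for line in config.ae_management:
        name = f"ae_management.{line}"
        lo, hi = rng_for(name, config.ae_management[line])
        specs.append(ParamSpec(name, config.ae_management[line], lo, hi, "gamma"))
    for name, base in (
        ("bsc_cost", config.bsc_cost_per_cycle),
        ("admin_iv_infusion", config.admin_iv_infusion),
    ):
        lo, hi = rng_for(name, base)
        specs.append(ParamSpec(name, base, lo, hi, "gamma"))

    for key, base in config.utilities.items():
        name = f"utility.{key}"
        lo, hi = rng_for(name, base)
        specs.append(
            ParamSpec(name, base, lo, hi, "beta", sd=config.psa_sd.get(name))
        )
    lo, hi = rng_for("ae_disutility", config.ae_disutility)
    specs.append(ParamSpec("ae_disutility", config.ae_disutility, lo, hi, "beta"))

    for group, values in (
        ("discontinuation", config.discontinuation),
        ("ae_mortality", config.ae_mortality),
    ):
        for key, base in values.items():
            if base <= 0.0:
                continue  # a zero probability has no beta representation
            name = f"{group}.{key}"
            lo, hi = rng_for(name, base)
            specs.append(ParamSpec(name, base, lo, min(hi, 1.0), "beta"))

    for name, base in (("start_age", config.start_age), ("weight_kg", config.weight_kg)):
        lo, hi = rng_for(name, base)
        specs.append(ParamSpec(name, base, lo, hi, "normal"))
    return specs


def sample_param(spec: ParamSpec, rng: np.random.Generator) -> float:
    """Draw one value for a parameter from its PSA distribution."""
    if spec.distribution == "fixed":
        return spec.base
    m, sd = spec.base, spec.sd_effective
    if sd <= 0:
        return m
    if spec.distribution == "gamma":
        k = (m / sd) ** 2
        theta = sd**2 / m
        return float(rng.gamma(k, theta))
    if spec.distribution == "beta":
        max_var = m * (1.0 - m)
        if sd**2 >= max_var:
            warnings.warn(
                f"{spec.name}: SD {sd:.3g} infeasible for beta mean {m:.3g}; clipped"
            )
            sd = 0.95 * np.sqrt(max_var)
        nu = max_var / sd**2 - 1.0
        return float(rng.beta(m * nu, (1.0 - m) * nu))
    if spec.distribution == "normal":
        return float(np.clip(rng.normal(m, sd), spec.low, spec.high))
    raise AssertionError(spec.distribution)


def _incremental(config: ModelConfig, n_patients: int, seed: int) -> IncrementalResult:
    res = run_cohort(config, n_patients, seed)
    return icer(res[ARMS[0]], res[ARMS[1]])


# ---------------------------------------------------------------------------
# One-way (tornado)
# ---------------------------------------------------------------------------

def one_way(
    config: ModelConfig,
    specs: list[ParamSpec],
    n_patients: int,
    seed: int,
) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's low and high bound.

    All runs reuse the same cohort seed (common random numbers). Rows are
    sorted by descending ICER span; invalid ranges are skipped with a
    warning.
    """
    if not specs:
        raise ValueError("no parameter specs supplied")
    base_inc = _incremental(config, n_patients, seed)
    rows = []
    for spec in specs:
        try:
            lo_inc = _incremental(set_param(config, spec.name, spec.low), n_patients, seed)
            hi_inc = _incremental(set_param(config, spec.name, spec.high), n_patients, seed)
        except (ValueError, KeyError) as exc:
            warnings.warn(f"one-way range for {spec.name!r} skipped: {exc}")
            continue
        rows.append(
            {
                "parameter": spec.name,
                "low": spec.low,
                "high": spec.high,
                "icer_low": lo_inc.icer_per_qaly,
                "icer_high": hi_inc.icer_per_qaly,
                "icer_base": base_inc.icer_per_qaly,
                "span": abs(hi_inc.icer_per_qaly - lo_inc.icer_per_qaly),
            }
        )
    out = pd.DataFrame(rows).sort_values("span", ascending=False, ignore_index=True)
    return out


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

def psa(
    config: ModelConfig,
    specs: list[ParamSpec],
    n_iterations: int,
    n_patients: int,
    seed: int,
) -> pd.DataFrame:
    """Monte-Carlo PSA: joint parameter draws, one cohort per iteration.

    Returns one row per iteration holding every drawn parameter value plus
    the incremental outcomes (``delta_cost``, ``delta_ly``, ``delta_qaly``,
    ``icer_per_qaly``). Reproducible: the same seed yields bit-identical
    samples.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iterations):
        cfg = config
        draw: dict[str, float] = {}
        for spec in specs:
            value = sample_param(spec, rng)
            draw[spec.name] = value
            cfg = set_param(cfg, spec.name, value)
        iter_seed = int(rng.integers(0, 2**31 - 1))
        inc = _incremental(cfg, n_patients, iter_seed)
        rows.append(
            {
                "iteration": it,
                "seed": iter_seed,
                **draw,
                "delta_cost": inc.delta_cost,
                "delta_ly": inc.delta_ly,
                "delta_qaly": inc.delta_qaly,
                "icer_per_qaly": inc.icer_per_qaly,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Scenario program
# ---------------------------------------------------------------------------

def scenario_price(
    config: ModelConfig,
    target: str,
    fraction: float,
    n_patients: int,
    seed: int,
) -> IncrementalResult:
    """Rescale a drug price (or a whole strategy's drug prices).

    ``target`` is a drug name (e.g. ``"nivolumab"``) or
    ``"strategy:nivolumab_cabozantinib"`` to scale every drug in that
    first-line regimen. ``fraction=1`` reproduces the base case.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must lie in (0, 1]")
    cfg = config.copy()
    if target.startswith("strategy:"):
        arm = target.split(":", 1)[1]
        drugs = {"nivolumab_cabozantinib": ("nivolumab", "cabozantinib")}.get(
            arm, (arm,)
        )
    else:
        drugs = (target,)
    for drug in drugs:
        if drug not in cfg.unit_prices:
            raise ValueError(f"unknown drug {drug!r}")
        cfg.unit_prices[drug] *= fraction
    return _incremental(cfg, n_patients, seed)


def scenario_horizon(
    config: ModelConfig, years: float, n_patients: int, seed: int
) -> IncrementalResult:
    """Truncate the time horizon; a horizon past the age cap is the base case."""
    if years <= 0:
        raise ValueError("horizon must be positive")
    cfg = config.copy()
    cfg.horizon_years = years
    return _incremental(cfg, n_patients, seed)


def scenario_bsc_switch(
    config: ModelConfig,
    p_switch_by_arm: dict[str, float],
    n_patients: int,
    seed: int,
) -> IncrementalResult:
    """Route a proportion of first-line exits directly to BSC, per arm."""
    cfg = config.copy()
    for arm, p in p_switch_by_arm.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError("switch probabilities must lie in [0, 1]")
        cfg.bsc_switch_prob[arm] = p
    return _incremental(cfg, n_patients, seed)
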