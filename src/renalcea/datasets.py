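"""Bundled fixtures and synthetic-data generators.

Everything the pipeline consumes can be produced here without downloads:
the base-case configuration (shipped as a YAML file mirroring the source
input table), the Gompertz background-mortality fixture, and synthetic
"digitized" Kaplan-Meier curves with numbers-at-risk tables for exercising
the pseudo-IPD reconstruction.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .config import ModelConfig, config_from_dict
from .km import DigitizedCurve, km_estimate
from .lifetables import LifeTable, make_life_table  # re-exported
from .survival import ParametricSurvival, make_ipd

__all__ = [
    "default_config",
    "make_life_table",
    "synth_km_digitization",
]


def _uniform_censor_bound(model: ParametricSurvival, censor_rate: float) -> float:
    """Upper bound of a U(0, c_max) censoring law giving the target
    expected censored fraction P(C < T) = (1/c_max) * int_0^c_max S."""
    from scipy import integrate, optimize

    def frac(c):
        val, _ = integrate.quad(model.survival, 0.0, c, limit=200)
        return val / c - censor_rate

    hi = model.median()
    while frac(hi) > 0:
        hi *= 2.0
        if hi > 1e7:
            raise ValueError("censor_rate unattainably low for this law")
    return float(optimize.brentq(frac, model.median() * 1e-3, hi))


def default_config() -> ModelConfig:
    """The full base-case configuration as shipped (the Table-1 fixture)."""
    import yaml

    ref = resources.files("renalcea").joinpath("data/base_case_inputs.yaml")
    with ref.open() as fh:
        return config_from_dict(yaml.safe_load(fh))


def synth_km_digitization(
    true_model: ParametricSurvival,
    n: int,
    censor_rate: float = 0.0,
    grid_size: int = 40,
    n_risk_intervals: int = 4,
    seed: int = 0,
) -> tuple[DigitizedCurve, pd.DataFrame]:
    """Emulate a digitized survival figure from a known generating law.

    Simulates ``n`` subjects from ``true_model`` under independent uniform
    censoring ``C ~ U(0, c_max)``, with ``c_max`` solved so the expected
    censored fraction equals ``censor_rate``. The Kaplan-Meier curve of the
    sample is then digitized on a ``grid_size``-point grid whose clicks
    follow equally spaced survival levels (dense where the curve moves, as
    a human digitizer would click) and a numbers-at-risk table with
    ``n_risk_intervals`` intervals is emitted, alongside the ground-truth
    IPD.
    """
    if n < 20:
        raise ValueError("need n >= 20 subjects")
    if not 0.0 <= censor_rate < 1.0:
        raise ValueError("censor_rate must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    t_event = true_model.rvs(n, rng)
    if censor_rate > 0.0:
        c_max = _uniform_censor_bound(true_model, censor_rate)
        c = rng.random(n) * c_max
        time = np.minimum(t_event, c)
        event = (t_event <= c).astype(int)
    else:
        time = t_event
        event = np.ones(n, dtype=int)
    ipd = make_ipd(time, event)

    km = km_estimate(ipd)
    t_max = float(np.quantile(time, 0.98))
    # click times at equally spaced survival levels between 1 and S(t_max)
    levels = np.linspace(1.0, float(km(t_max)), grid_size)
    step_t, step_s = km.times, km.survival
    grid = np.array(
        [step_t[np.argmax(step_s <= lv + 1e-12)] for lv in levels]
    )
    grid = np.unique(np.clip(grid, 0.0, t_max))
    curve_s = km(grid)

    risk_times = np.linspace(0.0, t_max, n_risk_intervals + 1)[:-1]
    n_at_risk = np.array([(time >= rt).sum() for rt in risk_times])
    curve = DigitizedCurve(
        times=grid,
        survival=curve_s,
        risk_times=risk_times,
        n_at_risk=n_at_risk,
        total_events=int(((time <= t_max) & (event == 1)).sum()),
    )
    return curve, ipd
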