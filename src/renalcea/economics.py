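"""Incremental cost-effectiveness aggregation.

Implements the decision-analytic summary layer: per-arm discounted mean
outcomes, incremental cost-effectiveness ratios (ICERs), net monetary
benefit (NMB), and cost-effectiveness acceptability curves (CEACs).
Currency is 2021 USD throughout; internal arithmetic is at full precision
and the ICER is conventionally reported to the nearest dollar.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["ArmResult", "IncrementalResult", "icer", "nmb", "ceac"]


@dataclass(frozen=True)
class ArmResult:
    """Discounted mean outcomes for one strategy arm."""

    arm: str
    mean_cost: float
    mean_ly: float
    mean_qaly: float
    n_patients: int
    seed: int | None = None
    mean_cost_undiscounted: float | None = None
    mean_ly_undiscounted: float | None = None
    mean_qaly_undiscounted: float | None = None

    def __post_init__(self) -> None:
        if min(self.mean_cost, self.mean_ly, self.mean_qaly) < 0:
            raise ValueError("arm outcomes must be nonnegative")
        if self.mean_qaly > self.mean_ly + 1e-9:
            raise ValueError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class IncrementalResult:
    """Incremental outcomes of an intervention over a comparator."""

    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float   # NaN when delta_qaly == 0
    icer_per_ly: float     # NaN when delta_ly == 0
    dominance: str         # "", "dominant", "dominated", "undefined"


def icer(a: ArmResult, b: ArmResult) -> IncrementalResult:
    """Incremental cost-effectiveness of arm ``a`` versus arm ``b``.

    ``dominant`` flags a cheaper-and-more-effective intervention,
    ``dominated`` the reverse; a zero QALY difference yields an undefined
    ICER (NaN) rather than a number.
    """
    dc = a.mean_cost - b.mean_cost
    dq = a.mean_qaly - b.mean_qaly
    dl = a.mean_ly - b.mean_ly
    if dq == 0.0:
        flag = "undefined"
        per_qaly = float("nan")
    else:
        per_qaly = dc / dq
        if dc <= 0.0 and dq > 0.0:
            flag = "dominant"
        elif dc >= 0.0 and dq < 0.0:
            flag = "dominated"
        else:
            flag = ""
    per_ly = dc / dl if dl != 0.0 else float("nan")
    return IncrementalResult(
        delta_cost=dc, delta_ly=dl, delta_qaly=dq,
        icer_per_qaly=per_qaly, icer_per_ly=per_ly, dominance=flag,
    )


def nmb(res: ArmResult, wtp: float) -> float:
    """Net monetary benefit ``wtp * QALY - cost`` at a willingness to pay."""
    if wtp < 0:
        raise ValueError("willingness to pay must be nonnegative")
    return wtp * res.mean_qaly - res.mean_cost


def ceac(samples, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability curves from PSA samples.

    Parameters
    ----------
    samples:
        A sequence of :class:`IncrementalResult` (or any objects/rows with
        ``delta_cost`` and ``delta_qaly``), one per PSA iteration.
    wtp_grid:
        Willingness-to-pay thresholds (USD/QALY) at which to evaluate.

    Returns
    -------
    DataFrame with columns ``wtp``, ``p_intervention``, ``p_comparator``;
    at each threshold the intervention probability is the fraction of
    samples with strictly positive incremental NMB, and the two
    probabilities sum to one.
    """
    wtp_grid = np.asarray(wtp_grid, dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("empty willingness-to-pay grid")
    if isinstance(samples, pd.DataFrame):
        dc = samples["delta_cost"].to_numpy(dtype=float)
        dq = samples["delta_qaly"].to_numpy(dtype=float)
    else:
        samples = list(samples)
        if not samples:
            raise ValueError("need at least one PSA sample")
        dc = np.array([s.delta_cost for s in samples])
        dq = np.array([s.delta_qaly for s in samples])
    inb = dq[None, :] * wtp_grid[:, None] - dc[None, :]
    p_int = (inb > 0).mean(axis=1)
    return pd.DataFrame(
        {"wtp": wtp_grid, "p_intervention": p_int, "p_comparator": 1.0 - p_int}
    )
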