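"""Kaplan-Meier estimation and pseudo-IPD reconstruction from digitized curves.

Published survival figures can be turned back into approximate individual
patient data (pseudo-IPD) given (a) digitized curve coordinates and (b) the
numbers-at-risk table printed under the figure. The reconstruction here
follows the iterative interval-by-interval scheme of Guyot-style curve
inversion: within each risk-table interval, censoring is assumed uniform,
the censor count is adjusted until the implied number at risk at the start
of the next interval matches the published one, and event counts are read
off the digitized survival ratios. If the total event count is published it
is used to adjust the final interval.

The product-limit estimator implemented here doubles as the validation
oracle: the KM curve of the reconstructed pseudo-IPD should track the
digitized input curve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import make_ipd

__all__ = ["DigitizedCurve", "KaplanMeierEstimate", "km_estimate", "reconstruct_ipd"]


# ---------------------------------------------------------------------------
# Product-limit estimator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KaplanMeierEstimate:
    """Right-continuous product-limit step function.

    ``times`` holds the distinct event times (prepended with 0) and
    ``survival`` the step values S(t) for t in ``[times[i], times[i+1])``.
    """

    times: np.ndarray
    survival: np.ndarray

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.times, t, side="right") - 1
        idx = np.clip(idx, 0, len(self.times) - 1)
        out = self.survival[idx]
        return float(out) if out.ndim == 0 else out


def km_estimate(ipd: pd.DataFrame) -> KaplanMeierEstimate:
    """Kaplan-Meier product-limit estimate of right-censored IPD."""
    if len(ipd) == 0:
        raise ValueError("IPD must be nonempty")
    time = np.asarray(ipd["time_months"], dtype=float)
    event = np.asarray(ipd["event"], dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    ev_times = np.unique(time[event == 1])
    n = len(time)
    s = 1.0
    times = [0.0]
    surv = [1.0]
    for t in ev_times:
        at_risk = np.sum(time >= t)
        d = np.sum((time == t) & (event == 1))
        s *= 1.0 - d / at_risk
        times.append(t)
        surv.append(s)
    return KaplanMeierEstimate(np.asarray(times), np.asarray(surv))


# ---------------------------------------------------------------------------
# Digitized curve container
# ---------------------------------------------------------------------------

@dataclass
class DigitizedCurve:
    """Digitized survival-curve coordinates plus a numbers-at-risk table.

    Parameters
    ----------
    times, survival:
        Ordered curve coordinates; the first point must be (0, 1) (it is
        inserted if missing). Non-monotone survival readings (digitization
        jitter) are repaired by isotonic clipping with a warning; duplicate
        times are collapsed keeping the lower survival value.
    risk_times, n_at_risk:
        The numbers-at-risk table; counts must be nonincreasing.
    total_events:
        Optional published total event count used to adjust the final
        interval of the reconstruction.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    n_at_risk: np.ndarray
    total_events: int | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.survival = np.asarray(self.survival, dtype=float)
        self.risk_times = np.asarray(self.risk_times, dtype=float)
        self.n_at_risk = np.asarray(self.n_at_risk, dtype=int)
        if len(self.risk_times) < 2:
            raise ValueError("need at least 2 risk-table entries")
        if np.any(self.survival > 1.0 + 1e-9) or np.any(self.survival < 0):
            raise ValueError("survival values must lie in [0, 1]")
        if np.any(self.times < 0) or np.any(self.risk_times < 0):
            raise ValueError("times must be nonnegative")
        if np.any(np.diff(self.n_at_risk) > 0):
            raise ValueError("numbers at risk must be nonincreasing")
        order = np.argsort(self.times, kind="stable")
        self.times, self.survival = self.times[order], self.survival[order]
        # collapse duplicate times keeping the lower survival value
        if len(np.unique(self.times)) != len(self.times):
            df = pd.DataFrame({"t": self.times, "s": self.survival})
            df = df.groupby("t", as_index=False)["s"].min()
            self.times, self.survival = df["t"].to_numpy(), df["s"].to_numpy()
        if self.times[0] > 0:
            self.times = np.insert(self.times, 0, 0.0)
            self.survival = np.insert(self.survival, 0, 1.0)
        self.survival[0] = 1.0
        mono = np.minimum.accumulate(self.survival)
        if np.any(mono < self.survival):
            warnings.warn("non-monotone digitized survival repaired by isotonic clipping")
            self.survival = mono

    @classmethod
    def from_csv(cls, curve_csv, risk_csv, total_events: int | None = None):
        """Load from ``curve.csv`` (time,survival) and ``risk.csv`` (time,n_at_risk)."""
        c = pd.read_csv(curve_csv)
        r = pd.read_csv(risk_csv)
        return cls(
            c["time"].to_numpy(), c["survival"].to_numpy(),
            r["time"].to_numpy(), r["n_at_risk"].to_numpy(),
            total_events=total_events,
        )


# ---------------------------------------------------------------------------
# Reconstruction
# ---------------------------------------------------------------------------

def _distribute_censor_times(c: int, t_lo: float, t_hi: float) -> np.ndarray:
    """Place ``c`` censor times uniformly on (t_lo, t_hi)."""
    if c <= 0:
        return np.empty(0)
    return t_lo + np.arange(1, c + 1) * (t_hi - t_lo) / (c + 1)


def reconstruct_ipd(
    curve: DigitizedCurve, max_iter: int = 200, diagnostics: dict | None = None
) -> pd.DataFrame:
    """Reconstruct pseudo-IPD from a digitized curve and risk table.

    Returns an IPD frame (``time_months``, ``event``) whose Kaplan-Meier
    estimate tracks the digitized curve; the number of records at time 0
    equals the first risk-table entry, and when ``total_events`` is given
    the reconstructed event count matches it exactly.
    """
    t = curve.times
    S = curve.survival
    K = len(t)
    rt, nr = curve.risk_times, curve.n_at_risk
    # drop risk entries beyond the digitized support
    keep = rt <= t[-1] + 1e-12
    rt, nr = rt[keep], nr[keep]
    if len(rt) < 2:
        raise ValueError("risk table does not overlap the digitized grid")
    n_int = len(rt)
    lower = np.searchsorted(t, rt, side="left")
    upper = np.append(lower[1:] - 1, K - 1)

    d = np.zeros(K, dtype=int)       # events at each click
    cen = np.zeros(K, dtype=int)     # censorings in [t_k, t_{k+1})
    n_hat = np.zeros(K + 1, dtype=float)
    km_hat = np.ones(K)
    n_hat[lower[0]] = nr[0]
    n_censor = np.zeros(n_int, dtype=int)
    last_i = 0

    def _interval_pass(i: int, last: int) -> int:
        """Forward pass over interval i given cen[]; returns last event index."""
        n_hat[lower[i]] = nr[i]
        for k in range(lower[i], upper[i] + 1):
            if i == 0 and k == lower[0]:
                d[k] = 0
                km_hat[k] = 1.0
            else:
                if km_hat[last] > 0:
                    d[k] = int(round(n_hat[k] * (1.0 - S[k] / km_hat[last])))
                else:
                    d[k] = 0
                d[k] = int(np.clip(d[k], 0, n_hat[k]))
                # keep the risk set alive wherever the curve is positive
                if S[k] > 0.0 and d[k] == n_hat[k] and d[k] > 0:
                    d[k] -= 1
                if n_hat[k] > 0:
                    km_hat[k] = km_hat[last] * (1.0 - d[k] / n_hat[k])
                else:
                    km_hat[k] = 0.0
            n_hat[k + 1] = n_hat[k] - d[k] - cen[k]
            if n_hat[k + 1] < 0:
                n_hat[k + 1] = 0
                cen[k] = int(n_hat[k] - d[k])
            if d[k] != 0:
                last = k
        return last

    def _spread_censor(i: int) -> None:
        cen[lower[i]: upper[i] + 1] = 0
        if n_censor[i] <= 0:
            n_censor[i] = max(n_censor[i], 0)
            return
        # censor times spread over the interval's click span; a censor in
        # [t_k, t_{k+1}) leaves the risk set after click k
        t_lo = t[lower[i]]
        t_hi = t[lower[i + 1]] if i + 1 < n_int else t[upper[i]]
        ct = _distribute_censor_times(n_censor[i], t_lo, t_hi)
        if t_hi <= t_lo:
            ct = np.full(n_censor[i], t_lo)
        idx = np.clip(np.searchsorted(t, ct, side="right") - 1, lower[i], upper[i])
        for j in idx:
            cen[j] += 1

    # -- intervals with a known terminal number at risk
    for i in range(n_int - 1):
        n_censor[i] = int(round(nr[i] * S[lower[i + 1]] / S[lower[i]] - nr[i + 1]))
        for _ in range(max_iter):
            clamped = n_censor[i] <= 0
            if clamped:
                n_censor[i] = 0
            _spread_censor(i)
            last = _interval_pass(i, last_i)
            gap = int(n_hat[lower[i + 1]] - nr[i + 1])
            if gap == 0 or (clamped and gap < 0):
                break
            n_censor[i] += gap
        last_i = last

    # -- final interval: no terminal risk count; carry the prior censor rate
    i = n_int - 1
    last_start = last_i
    if n_int > 1 and t[upper[i]] > rt[i]:
        prior_span = rt[i] - t[lower[0]]
        prior_cen = int(cen[: lower[i]].sum())
        rate = prior_cen / prior_span if prior_span > 0 else 0.0
        n_censor[i] = int(min(round(rate * (t[upper[i]] - rt[i])), nr[i]))
    _spread_censor(i)
    last_i = _interval_pass(i, last_start)

    # -- adjust the final interval's censoring until the reconstructed event
    # total matches a published one (the event/censor split there is
    # otherwise unidentified)
    if curve.total_events is not None:
        target = int(curve.total_events)
        seen: set[int] = set()
        for _ in range(max_iter):
            resid = target - int(d.sum())
            if resid == 0 or n_censor[i] in seen:
                break
            if resid > 0 and n_censor[i] <= 0:
                break
            if resid < 0 and n_censor[i] >= nr[i]:
                break
            seen.add(n_censor[i])
            n_censor[i] = int(np.clip(n_censor[i] - resid, 0, nr[i]))
            _spread_censor(i)
            last_i = _interval_pass(i, last_start)

    # -- assemble records from the per-click flows; the initial cohort size
    # is conserved by construction
    remaining = int(nr[0] - d.sum() - cen.sum())
    while remaining < 0:  # trim late censors if interval resets overfilled
        k = int(np.flatnonzero(cen > 0)[-1])
        trim = min(cen[k], -remaining)
        cen[k] -= trim
        remaining += trim
    times_out: list[float] = []
    events_out: list[int] = []
    for k in range(K):
        times_out.extend([t[k]] * int(d[k]))
        events_out.extend([1] * int(d[k]))
        if cen[k] > 0:
            t_next = t[k + 1] if k + 1 < K else t[k]
            if t_next > t[k]:
                ct = _distribute_censor_times(int(cen[k]), t[k], t_next)
            else:
                ct = np.full(int(cen[k]), t[k])
            times_out.extend(float(x) for x in ct)
            events_out.extend([0] * int(cen[k]))
    # patients still at risk at the end of the digitized curve
    times_out.extend([t[-1]] * remaining)
    events_out.extend([0] * remaining)
    times_arr = np.asarray(times_out)
    events_arr = np.asarray(events_out)

    # -- enforce a published total event count by relabelling records;
    # flips keep every at-risk trajectory intact, and flipping the earliest
    # records perturbs the curve least (early risk sets are largest)
    if curve.total_events is not None:
        target = int(curve.total_events)
        resid = target - int(events_arr.sum())
        if resid < 0:  # too many events: earliest events become censorings
            ev_idx = np.flatnonzero(events_arr == 1)
            flip = ev_idx[np.argsort(times_arr[ev_idx])][:-resid]
            events_arr[flip] = 0
        elif resid > 0:  # too few: earliest censorings become events
            cn_idx = np.flatnonzero(events_arr == 0)
            flip = cn_idx[np.argsort(times_arr[cn_idx])][:resid]
            events_arr[flip] = 1

    if diagnostics is not None:
        diagnostics.update(
            d=d.copy(), cen=cen.copy(), n_hat=n_hat.copy(), lower=lower,
            upper=upper, n_censor=n_censor.copy(), km_hat=km_hat.copy(),
        )
    ipd = make_ipd(times_arr, events_arr)
    return ipd.sort_values("time_months", ignore_index=True)
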