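"""Parametric survival laws for treatment-line extrapolation.

Each treatment line in the sequencing model is driven by a two-parameter
(or, for the exponential, one-parameter) survival law fitted to
progression-free or overall survival data. This module provides the law
itself (:class:`ParametricSurvival`), per-cycle transition probabilities
derived from it, right-censored maximum-likelihood fitting, and AIC-based
family selection.

Conventions
-----------
* Time is measured in **months** throughout.
* ``scale`` carries the time unit; ``shape`` is dimensionless.
* The log-logistic law uses ``S(t) = 1 / (1 + (t/scale)^shape)`` so that the
  median equals the scale exactly.
* The exponential law is parameterised by its **mean** survival time
  (``scale``); the event rate is ``1/scale``.

Individual patient data (IPD) are represented as a :class:`pandas.DataFrame`
with columns ``time_months`` (nonnegative float) and ``event``
(1 = event, 0 = right-censored).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "FAMILIES",
    "ParametricSurvival",
    "FitResult",
    "survival_at",
    "percycle_transition_prob",
    "median_survival",
    "fit_parametric",
    "aic_select",
    "pool_ipd",
    "make_ipd",
    "read_ipd",
    "write_ipd",
]

#: Supported distribution families, in the fixed order used for tie-breaking.
FAMILIES: tuple[str, ...] = (
    "exponential",
    "weibull",
    "lognormal",
    "gamma",
    "loglogistic",
)

_N_PARAMS = {
    "exponential": 1,
    "weibull": 2,
    "lognormal": 2,
    "gamma": 2,
    "loglogistic": 2,
}


def _frozen(family: str, shape: float, scale: float):
    """Return the scipy frozen distribution for a (shape, scale) pair."""
    if family == "exponential":
        return stats.expon(scale=scale)
    if family == "weibull":
        return stats.weibull_min(shape, scale=scale)
    if family == "lognormal":
        # shape = sigma of log-time, scale = exp(mu)
        return stats.lognorm(shape, scale=scale)
    if family == "gamma":
        return stats.gamma(shape, scale=scale)
    if family == "loglogistic":
        return stats.fisk(shape, scale=scale)
    raise ValueError(f"unknown survival family {family!r}")


@dataclass(frozen=True)
class ParametricSurvival:
    """A parametric survival-time law for one treatment line.

    Parameters
    ----------
    family:
        One of :data:`FAMILIES`.
    shape:
        Dimensionless shape parameter (ignored, and conventionally 1.0,
        for the exponential family).
    scale:
        Scale parameter in months. For the exponential family this is the
        mean survival time.
    """

    family: str
    shape: float
    scale: float

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown survival family {self.family!r}")
        if not (self.shape > 0 and np.isfinite(self.shape)):
            raise ValueError("shape must be strictly positive and finite")
        if not (self.scale > 0 and np.isfinite(self.scale)):
            raise ValueError("scale must be strictly positive and finite")

    # -- construction helpers -------------------------------------------------
    @classmethod
    def exponential(cls, *, mean: float | None = None, rate: float | None = None):
        """Exponential law from either its mean survival time or event rate."""
        if (mean is None) == (rate is None):
            raise ValueError("give exactly one of mean= or rate=")
        scale = mean if mean is not None else 1.0 / rate
        return cls("exponential", 1.0, float(scale))

    # -- law ------------------------------------------------------------------
    def survival(self, t):
        """Survival probability S(t) for time(s) ``t`` in months."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        out = _frozen(self.family, self.shape, self.scale).sf(t)
        return float(out) if out.ndim == 0 else out

    def hazard(self, t):
        """Instantaneous hazard h(t) = f(t)/S(t)."""
        t = np.asarray(t, dtype=float)
        if np.any(t < 0):
            raise ValueError("time must be nonnegative")
        d = _frozen(self.family, self.shape, self.scale)
        with np.errstate(over="ignore"):
            out = np.exp(d.logpdf(t) - d.logsf(t))
        return float(out) if out.ndim == 0 else out

    def transition_prob(self, t: float, delta: float):
        """Per-cycle transition probability ``1 - S(t+delta)/S(t)``."""
        return percycle_transition_prob(self, t, delta)

    def median(self) -> float:
        """Time at which S(t) = 1/2."""
        return median_survival(self)

    def rvs(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Draw ``n`` survival times."""
        return _frozen(self.family, self.shape, self.scale).rvs(
            size=n, random_state=rng
        )

    # -- serialization --------------------------------------------------------
    def to_dict(self) -> dict:
        return {"family": self.family, "shape": self.shape, "scale": self.scale}

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_dict(cls, d: dict) -> "ParametricSurvival":
        return cls(d["family"], float(d.get("shape", 1.0)), float(d["scale"]))

    @classmethod
    def from_json(cls, s: str) -> "ParametricSurvival":
        return cls.from_dict(json.loads(s))


# ---------------------------------------------------------------------------
# Module-level operations
# ---------------------------------------------------------------------------

def survival_at(model: ParametricSurvival, t) -> float:
    """Evaluate S(t); thin functional wrapper over the model method."""
    return model.survival(t)


def percycle_transition_prob(model: ParametricSurvival, t, delta: float):
    """Probability of leaving the state during ``(t, t + delta]``.

    This is the standard discretisation ``tp(t) = 1 - S(t+delta)/S(t)``;
    for the exponential family it is independent of ``t`` (memorylessness).
    """
    if delta <= 0:
        raise ValueError("delta must be positive")
    t = np.asarray(t, dtype=float)
    st = model.survival(t)
    if np.any(np.asarray(st) <= 0):
        raise ValueError("S(t) = 0: survival support exhausted at t")
    out = 1.0 - model.survival(t + delta) / st
    out = np.clip(out, 0.0, 1.0)
    return float(out) if np.ndim(out) == 0 else out


def median_survival(model: ParametricSurvival) -> float:
    """Median survival time in months.

    Closed forms are used where they exist (exponential, Weibull,
    lognormal, log-logistic — for which the median equals the scale);
    the gamma median is found numerically to ``|S - 1/2| < 1e-10``.
    """
    a, b = model.shape, model.scale
    if model.family == "exponential":
        return b * np.log(2.0)
    if model.family == "weibull":
        return b * np.log(2.0) ** (1.0 / a)
    if model.family == "lognormal":
        return b  # exp(mu)
    if model.family == "loglogistic":
        return b
    # gamma: bisection-style root find on S(t) - 1/2
    f = lambda t: model.survival(t) - 0.5
    hi = b * max(a, 1.0)
    while f(hi) > 0:
        hi *= 2.0
    return float(optimize.brentq(f, 0.0, hi, xtol=1e-12, rtol=1e-15))


# ---------------------------------------------------------------------------
# IPD containers
# ---------------------------------------------------------------------------

def make_ipd(time, event) -> pd.DataFrame:
    """Assemble an IPD frame from time/event arrays, with validation."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event)
    if time.shape != event.shape:
        raise ValueError("time and event must have the same length")
    if np.any(~np.isfinite(time)) or np.any(time < 0):
        raise ValueError("times must be finite and nonnegative")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event must be binary (0 = censored, 1 = event)")
    return pd.DataFrame({"time_months": time, "event": event.astype(int)})


def pool_ipd(a: pd.DataFrame, b: pd.DataFrame) -> pd.DataFrame:
    """Pool two IPD sets by concatenation (no reweighting)."""
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both IPD sets must be nonempty")
    return pd.concat([a, b], ignore_index=True)


def read_ipd(path) -> pd.DataFrame:
    """Read IPD from a two-column CSV (time_months, event)."""
    return make_ipd(*(lambda d: (d["time_months"], d["event"]))(pd.read_csv(path)))


def write_ipd(ipd: pd.DataFrame, path) -> None:
    ipd.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Maximum-likelihood fitting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FitResult:
    model: ParametricSurvival
    loglik: float
    n_params: int

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


def _censored_loglik(family, shape, scale, time, event) -> float:
    d = _frozen(family, shape, scale)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        ll = np.where(event == 1, d.logpdf(time), d.logsf(time))
    if np.any(~np.isfinite(ll)):
        return -np.inf
    return float(ll.sum())


def fit_parametric(ipd: pd.DataFrame, family: str) -> FitResult:
    """Fit one family to right-censored IPD by maximum likelihood.

    Optimisation runs on log-parameters with a bounded quasi-Newton method
    from three starting points, guarding against local optima; the reported
    log-likelihood is the censored-data log-likelihood.

    Raises
    ------
    ValueError
        If fewer than two events are present, or the optimiser fails.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown survival family {family!r}")
    time = np.asarray(ipd["time_months"], dtype=float)
    event = np.asarray(ipd["event"], dtype=int)
    if event.sum() < 2:
        raise ValueError("need at least 2 events to fit a survival law")
    # strictly positive times for log-densities
    time = np.maximum(time, 1e-8)

    ev_t = time[event == 1]
    scale0 = float(np.mean(ev_t))
    k = _N_PARAMS[family]

    if k == 1:
        def nll(theta):
            return -_censored_loglik(family, 1.0, np.exp(theta[0]), time, event)
        starts = [[np.log(scale0 * f)] for f in (0.5, 1.0, 2.0)]
    else:
        def nll(theta):
            return -_censored_loglik(
                family, np.exp(theta[0]), np.exp(theta[1]), time, event
            )
        starts = [[np.log(s), np.log(scale0)] for s in (0.8, 1.5, 3.0)]

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=[(-20.0, 20.0)] * k,
            options={"ftol": 1e-12, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ValueError(f"maximum-likelihood fit failed for family {family!r}")

    if k == 1:
        model = ParametricSurvival(family, 1.0, float(np.exp(best.x[0])))
    else:
        model = ParametricSurvival(
            family, float(np.exp(best.x[0])), float(np.exp(best.x[1]))
        )
    return FitResult(model=model, loglik=-float(best.fun), n_params=k)


def aic_select(
    ipd: pd.DataFrame, families: Iterable[str] = FAMILIES
) -> list[FitResult]:
    """Fit several families and rank them by AIC (ascending).

    Ties are broken by fewer parameters, then by the fixed order of
    :data:`FAMILIES`. Families whose fit fails are excluded with a warning.
    """
    families = list(families)
    if not families:
        raise ValueError("no families requested")
    fits: list[FitResult] = []
    for fam in families:
        try:
            fits.append(fit_parametric(ipd, fam))
        except ValueError as exc:  # propagate only if nothing fits
            warnings.warn(f"family {fam!r} excluded from AIC ranking: {exc}")
    if not fits:
        raise ValueError("all requested families failed to fit")
    order = {fam: i for i, fam in enumerate(FAMILIES)}
    fits.sort(key=lambda f: (f.aic, f.n_params, order[f.model.family]))
    return fits
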