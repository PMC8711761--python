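"""Individual-patient discrete-cycle simulation of the treatment sequence.

Patients enter on first-line therapy (nivolumab+cabozantinib or sunitinib)
and move through a fixed sequence — axitinib, sorafenib, best supportive
care (BSC) — until death or the horizon. Each 42-day cycle resolves events
in a fixed priority order:

1. **death** — background mortality from the life table, one-time
   adverse-event (AE) mortality in the first cycle on a line, and (in BSC
   only) disease death from the BSC overall-survival law;
2. **progression** — the per-cycle progression-free-survival (PFS)
   transition probability at the patient's current time on the line;
3. **AE discontinuation** — a constant per-cycle hazard obtained by
   spreading the line's cumulative discontinuation probability over its
   fitted median PFS duration.

Progression or discontinuation advances the line index; at most one
transition happens per cycle. Disease mortality before BSC is carried
implicitly by progression through the sequence into BSC, whose
overall-survival law governs death there. Costs and utility-time accrue for
every cycle the patient begins alive, with events resolved at cycle end;
discounting uses the discrete per-cycle factor ``(1+r)^(-t_years)`` at
cycle end (a half-cycle toggle is available on the configuration).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ARMS, ModelConfig, drug_cost_per_cycle
from .economics import ArmResult
from .lifetables import background_death_prob
from .survival import ParametricSurvival

__all__ = [
    "TreatmentLine",
    "PatientTrajectory",
    "build_lines",
    "simulate_patient",
    "run_cohort",
    "expected_outcomes",
]

_LINE_UTILITY_KEYS = ("first_line", "second_line", "third_line", "bsc")


@dataclass(frozen=True)
class TreatmentLine:
    """Compiled per-line inputs for one position in the sequence."""

    name: str
    pfs_model: ParametricSurvival | None  # None for BSC
    os_model: ParametricSurvival | None   # BSC only
    discontinuation_prob: float           # cumulative over the line
    ae_mortality_prob: float              # one-time, first cycle on line
    ae_grade3plus_prob: float
    drug_cost_per_cycle: float
    admin_cost_per_cycle: float
    ae_management_cost: float             # one-time at line entry
    utility: float

    def __post_init__(self) -> None:
        for p in (
            self.discontinuation_prob,
            self.ae_mortality_prob,
            self.ae_grade3plus_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0, 1] on line {self.name}")
        if min(self.drug_cost_per_cycle, self.admin_cost_per_cycle,
               self.ae_management_cost) < 0:
            raise ValueError(f"negative cost on line {self.name}")
        if not 0.0 <= self.utility <= 1.0:
            raise ValueError(f"utility out of [0, 1] on line {self.name}")


def build_lines(config: ModelConfig, arm: str) -> list[TreatmentLine]:
    """Compile the four-line sequence for one strategy arm."""
    if arm not in ARMS:
        raise ValueError(f"unknown arm {arm!r}; expected one of {ARMS}")
    up, cd, w = config.unit_prices, config.cycle_days, config.weight_kg
    n_infusions = 3.0 * cd / 42.0 if arm == "nivolumab_cabozantinib" else 0.0
    seq = []
    for pos, regimen in enumerate((arm, "axitinib", "sorafenib")):
        seq.append(
            TreatmentLine(
                name=regimen,
                pfs_model=config.pfs[regimen],
                os_model=None,
                discontinuation_prob=config.discontinuation[regimen],
                ae_mortality_prob=config.ae_mortality[regimen],
                ae_grade3plus_prob=config.ae_grade3plus[regimen],
                drug_cost_per_cycle=drug_cost_per_cycle(regimen, up, w, cd),
                admin_cost_per_cycle=(
                    n_infusions * config.admin_iv_infusion if pos == 0 else 0.0
                ),
                ae_management_cost=config.ae_management[regimen],
                utility=config.utilities[_LINE_UTILITY_KEYS[pos]],
            )
        )
    seq.append(
        TreatmentLine(
            name="bsc",
            pfs_model=None,
            os_model=config.bsc_os,
            discontinuation_prob=0.0,
            ae_mortality_prob=0.0,
            ae_grade3plus_prob=0.0,
            drug_cost_per_cycle=config.bsc_cost_per_cycle,
            admin_cost_per_cycle=0.0,
            ae_management_cost=0.0,
            utility=config.utilities["bsc"],
        )
    )
    return seq


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

CAUSES = ("background_death", "ae_death", "disease_death", "horizon")


def _per_cycle_discontinuation(line: TreatmentLine, cycle_months: float) -> float:
    """Spread the cumulative AE-discontinuation probability over the
    line's median PFS as a constant per-cycle hazard."""
    if line.pfs_model is None or line.discontinuation_prob <= 0.0:
        return 0.0
    median = line.pfs_model.median()
    return 1.0 - (1.0 - line.discontinuation_prob) ** (cycle_months / median)


def _tp_grid(model: ParametricSurvival, t: np.ndarray, delta: float) -> np.ndarray:
    """Per-cycle transition probabilities over a time grid; where the
    survival support is already exhausted (S(t) = 0, unreachable states)
    the transition is certain."""
    st = model.survival(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        tp = np.where(st > 0.0, 1.0 - model.survival(t + delta) / st, 1.0)
    return np.clip(tp, 0.0, 1.0)


def _draws(n: int, n_cycles: int, seed: int) -> dict[str, np.ndarray]:
    """Pre-drawn uniforms; shared across arms for common random numbers."""
    rng = np.random.default_rng(seed)
    return {
        "death": rng.random((n, n_cycles)),
        "prog": rng.random((n, n_cycles)),
        "disc": rng.random((n, n_cycles)),
        "switch": rng.random(n),
    }


@dataclass
class _ArmArrays:
    """Per-patient accruals from one simulated arm."""

    cost: np.ndarray
    ly: np.ndarray
    qaly: np.ndarray
    cost_undiscounted: np.ndarray
    ly_undiscounted: np.ndarray
    qaly_undiscounted: np.ndarray
    cause: np.ndarray        # index into CAUSES
    cycles_alive: np.ndarray


def _simulate_arm(
    config: ModelConfig, arm: str, draws: dict, trace: list | None = None
) -> _ArmArrays:
    lines = build_lines(config, arm)
    n, T = draws["death"].shape
    dm = config.cycle_months
    dy = config.cycle_years
    r = config.discount_rate_annual

    # per-line precomputation over time-on-line k = 0..T-1
    k = np.arange(T, dtype=float) * dm
    tp_prog = np.zeros((4, T))
    for li, ln in enumerate(lines[:3]):
        tp_prog[li] = _tp_grid(ln.pfs_model, k, dm)
    tp_bsc = _tp_grid(lines[3].os_model, k, dm)
    p_disc = np.array([_per_cycle_discontinuation(ln, dm) for ln in lines])
    drug = np.array([ln.drug_cost_per_cycle + ln.admin_cost_per_cycle for ln in lines])
    aec = np.array([ln.ae_management_cost for ln in lines])
    util = np.array([ln.utility for ln in lines])
    ae_du = np.array(
        [config.ae_disutility * ln.ae_grade3plus_prob for ln in lines]
    )
    aem = np.array([ln.ae_mortality_prob for ln in lines])

    ages = config.start_age + np.arange(T) * dy
    p_bg = background_death_prob(ages, config.life_table, dm)
    t_disc = (np.arange(T) + (0.5 if config.half_cycle_correction else 1.0)) * dy
    df = (1.0 + r) ** (-t_disc)
    p_switch = config.bsc_switch_prob.get(arm, 0.0)

    line = np.zeros(n, dtype=int)      # 0..3; 4 = dead
    tol = np.zeros(n, dtype=int)       # cycles on current line
    cause = np.full(n, 3, dtype=int)   # default: horizon-capped
    cycles_alive = np.zeros(n, dtype=int)
    acc = {key: np.zeros(n) for key in
           ("cost", "ly", "qaly", "cost_u", "ly_u", "qaly_u")}

    for c in range(T):
        alive = line < 4
        if not alive.any():
            break
        li = line[alive]
        k_on = tol[alive]
        first = k_on == 0

        # -- accrual for the cycle (events resolve at cycle end)
        ccost = drug[li] + np.where(first, aec[li], 0.0)
        cq = util[li] * dy - np.where(first, ae_du[li], 0.0) * dy
        acc["cost_u"][alive] += ccost
        acc["qaly_u"][alive] += cq
        acc["ly_u"][alive] += dy
        acc["cost"][alive] += ccost * df[c]
        acc["qaly"][alive] += cq * df[c]
        acc["ly"][alive] += dy * df[c]
        cycles_alive[alive] += 1

        # -- death (background, one-time AE, BSC disease)
        p1 = np.full(li.shape, p_bg[c])
        p2 = np.where(first, aem[li], 0.0)
        p3 = np.where(li == 3, tp_bsc[k_on], 0.0)
        p_dead = 1.0 - (1.0 - p1) * (1.0 - p2) * (1.0 - p3)
        u = draws["death"][alive, c]
        dead = u < p_dead
        # cause attribution by nested thresholds on the same uniform
        cause_new = np.where(
            u < p1, 0, np.where(u < 1.0 - (1.0 - p1) * (1.0 - p2), 1, 2)
        )

        # -- progression, then AE discontinuation (at most one transition)
        on_tx = li < 3
        prog = on_tx & (draws["prog"][alive, c] < tp_prog[np.minimum(li, 2), k_on])
        disc = on_tx & ~prog & (draws["disc"][alive, c] < p_disc[li])
        move = (prog | disc) & ~dead
        to_bsc = move & (li == 0) & (draws["switch"][alive] < p_switch)

        new_line = li.copy()
        new_tol = k_on + 1
        new_line[move] = li[move] + 1
        new_line[to_bsc] = 3
        new_tol[move] = 0
        new_line[dead] = 4

        idx = np.flatnonzero(alive)
        line[idx] = new_line
        tol[idx] = new_tol
        cause[idx[dead]] = cause_new[dead]

        if trace is not None:
            trace.append(
                {
                    "cycle": c,
                    "line_index": int(li[0]),
                    "alive": True,
                    "cost": float(ccost[0]),
                    "utility_time": float(cq[0]),
                }
            )
            if dead[0]:
                trace.append(
                    {
                        "cycle": c,
                        "line_index": int(li[0]),
                        "alive": False,
                        "cost": 0.0,
                        "utility_time": 0.0,
                    }
                )

    return _ArmArrays(
        cost=acc["cost"], ly=acc["ly"], qaly=acc["qaly"],
        cost_undiscounted=acc["cost_u"], ly_undiscounted=acc["ly_u"],
        qaly_undiscounted=acc["qaly_u"], cause=cause, cycles_alive=cycles_alive,
    )


@dataclass
class PatientTrajectory:
    """Per-cycle audit record of one simulated patient."""

    records: pd.DataFrame           # cycle, line_index, alive, cost, utility_time
    terminal_cause: str
    cost_discounted: float
    ly_discounted: float
    qaly_discounted: float
    cost_undiscounted: float
    ly_undiscounted: float
    qaly_undiscounted: float


def simulate_patient(config: ModelConfig, arm: str, seed: int) -> PatientTrajectory:
    """Simulate a single patient, returning the full trajectory for audit.

    Uses the same uniform-draw layout as :func:`run_cohort`, so the
    accruals for ``seed`` equal a one-patient cohort run with that seed.
    """
    trace: list = []
    res = _simulate_arm(config, arm, _draws(1, config.n_cycles(), seed), trace)
    return PatientTrajectory(
        records=pd.DataFrame(trace),
        terminal_cause=CAUSES[int(res.cause[0])],
        cost_discounted=float(res.cost[0]),
        ly_discounted=float(res.ly[0]),
        qaly_discounted=float(res.qaly[0]),
        cost_undiscounted=float(res.cost_undiscounted[0]),
        ly_undiscounted=float(res.ly_undiscounted[0]),
        qaly_undiscounted=float(res.qaly_undiscounted[0]),
    )


def run_cohort(
    config: ModelConfig,
    n_patients: int,
    seed: int,
    arms: tuple[str, ...] = ARMS,
    return_patients: bool = False,
):
    """Simulate both strategy arms over a common cohort of patients.

    The same pre-drawn uniform streams are reused for every arm (common
    random numbers), which removes between-arm sampling noise from the
    incremental outcomes. Returns ``{arm: ArmResult}``; with
    ``return_patients=True`` each value is ``(ArmResult, per-patient arrays)``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    draws = _draws(n_patients, config.n_cycles(), seed)
    out = {}
    for arm in arms:
        res = _simulate_arm(config, arm, draws)
        arm_result = ArmResult(
            arm=arm,
            mean_cost=float(res.cost.mean()),
            mean_ly=float(res.ly.mean()),
            mean_qaly=float(res.qaly.mean()),
            n_patients=n_patients,
            seed=seed,
            mean_cost_undiscounted=float(res.cost_undiscounted.mean()),
            mean_ly_undiscounted=float(res.ly_undiscounted.mean()),
            mean_qaly_undiscounted=float(res.qaly_undiscounted.mean()),
        )
        out[arm] = (arm_result, res) if return_patients else arm_result
    return out


# ---------------------------------------------------------------------------
# Deterministic cohort expectation (independent of the random engine)
# ---------------------------------------------------------------------------

def expected_outcomes(config: ModelConfig, arm: str) -> dict[str, float]:
    """Exact expectation of the microsimulation by occupancy bookkeeping.

    Tracks the joint distribution of (line, cycles-on-line) over cycles and
    accumulates expected accruals. Useful as a fast deterministic summary
    and as an oracle for the stochastic engine, which should converge to
    these values as the cohort grows.
    """
    lines = build_lines(config, arm)
    T = config.n_cycles()
    dm, dy, r = config.cycle_months, config.cycle_years, config.discount_rate_annual

    k = np.arange(T, dtype=float) * dm
    tp_prog = [_tp_grid(ln.pfs_model, k, dm) for ln in lines[:3]]
    tp_bsc = _tp_grid(lines[3].os_model, k, dm)
    p_disc = [_per_cycle_discontinuation(ln, dm) for ln in lines]
    p_switch = config.bsc_switch_prob.get(arm, 0.0)
    ages = config.start_age + np.arange(T) * dy
    p_bg = background_death_prob(ages, config.life_table, dm)
    t_disc = (np.arange(T) + (0.5 if config.half_cycle_correction else 1.0)) * dy
    df = (1.0 + r) ** (-t_disc)

    occ = np.zeros((4, T + 1))
    occ[0, 0] = 1.0
    totals = {key: 0.0 for key in
              ("cost", "ly", "qaly", "cost_undiscounted", "ly_undiscounted",
               "qaly_undiscounted")}
    for c in range(T):
        new = np.zeros_like(occ)
        ccost = cq = cly = 0.0
        for li, ln in enumerate(lines):
            p_line = occ[li]
            mass = p_line.sum()
            if mass <= 1e-15:
                continue
            firstmass = p_line[0]
            ccost += mass * (ln.drug_cost_per_cycle + ln.admin_cost_per_cycle)
            ccost += firstmass * ln.ae_management_cost
            cq += mass * ln.utility * dy
            cq -= firstmass * config.ae_disutility * ln.ae_grade3plus_prob * dy
            cly += mass * dy
            ks = np.flatnonzero(p_line > 0)
            p2 = np.where(ks == 0, ln.ae_mortality_prob, 0.0)
            if li == 3:
                p3 = tp_bsc[np.minimum(ks, T - 1)]
                p_alive = (1 - p_bg[c]) * (1 - p3)
                new[3, ks + 1] += p_line[ks] * p_alive
            else:
                p_alive = (1 - p_bg[c]) * (1 - p2)
                pp = tp_prog[li][np.minimum(ks, T - 1)]
                p_move = 1.0 - (1.0 - pp) * (1.0 - p_disc[li])
                stay = p_line[ks] * p_alive * (1.0 - p_move)
                go = p_line[ks] * p_alive * p_move
                new[li, ks + 1] += stay
                if li == 0 and p_switch > 0:
                    new[3, 0] += go.sum() * p_switch
                    new[1, 0] += go.sum() * (1 - p_switch)
                else:
                    new[li + 1, 0] += go.sum()
        totals["cost_undiscounted"] += ccost
        totals["qaly_undiscounted"] += cq
        totals["ly_undiscounted"] += cly
        totals["cost"] += ccost * df[c]
        totals["qaly"] += cq * df[c]
        totals["ly"] += cly * df[c]
        occ = new
        if occ.sum() < 1e-12:
            break
    return totals
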