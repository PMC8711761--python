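"""Microsimulation engine: accrual arithmetic, event resolution, oracles."""

import numpy as np
import pytest
from scipy import integrate

import renalcea as rc
from renalcea.config import set_param
from renalcea.microsim import CAUSES, build_lines


def _near_zero_mortality_config(config):
    """Copy of the base case with background mortality effectively off."""
    cfg = config.copy()
    cfg.life_table = rc.make_life_table(B=1e-15, c=1.0001)
    for k in cfg.ae_mortality:
        cfg.ae_mortality[k] = 0.0
    return cfg


class TestDrugCosts:
    def test_nivolumab_three_doses_per_cycle(self, config):
        # 3 x 6,849.84 for the IV component; cabozantinib 40/60 x 491.30/day
        cost = rc.drug_cost_per_cycle("nivolumab_cabozantinib", config.unit_prices)
        assert cost == pytest.approx(3 * 6849.84 + 42 * 491.30 * 40 / 60)

    def test_sunitinib_four_weeks_on(self, config):
        cost = rc.drug_cost_per_cycle("sunitinib", config.unit_prices)
        assert cost == pytest.approx(28 * 623.08)

    def test_later_lines_and_bsc(self, config):
        assert rc.drug_cost_per_cycle("axitinib", config.unit_prices) == pytest.approx(
            2 * 42 * 265.05
        )
        assert rc.drug_cost_per_cycle("sorafenib", config.unit_prices) == pytest.approx(
            4 * 42 * 174.0
        )
        assert rc.drug_cost_per_cycle("bsc", config.unit_prices) == 0.0

    def test_zero_priced_regimen(self, config):
        prices = {k: 0.0 for k in config.unit_prices}
        assert rc.drug_cost_per_cycle("sunitinib", prices) == 0.0

    def test_unknown_regimen_rejected(self, config):
        with pytest.raises(ValueError):
            rc.drug_cost_per_cycle("bevacizumab", config.unit_prices)


class TestBackgroundMortality:
    def test_twelve_month_delta_is_identity(self, config):
        lt = config.life_table
        q = lt.annual_q(70)
        assert rc.background_death_prob(70, lt, 12.0) == pytest.approx(q, rel=1e-12)

    def test_constant_hazard_rescaling(self, config):
        lt = rc.LifeTable(np.array([62]), np.array([0.01]))
        p = rc.background_death_prob(62, lt, 1.3799)
        assert p == pytest.approx(1 - 0.99 ** (1.3799 / 12.0), rel=1e-12)

    def test_ages_beyond_table_use_terminal_row(self, config):
        lt = config.life_table
        assert lt.annual_q(150) == lt.q_annual[-1]


class TestTrajectories:
    def test_degenerate_no_transition_closed_form(self, config):
        cfg = _near_zero_mortality_config(config)
        # freeze every transition: no progression, no discontinuation
        for k in cfg.discontinuation:
            cfg.discontinuation[k] = 0.0
        for k in cfg.pfs:
            cfg.pfs[k] = rc.ParametricSurvival("loglogistic", 1.5, 1e9)
        cfg.horizon_years = 5.0
        cfg.discount_rate_annual = 0.0
        traj = rc.simulate_patient(cfg, rc.ARM_SUNITINIB, seed=3)
        H = cfg.n_cycles()
        u1 = cfg.utilities["first_line"]
        du = cfg.ae_disutility * cfg.ae_grade3plus["sunitinib"]
        expected_q = H * cfg.cycle_years * u1 - du * cfg.cycle_years
        assert traj.terminal_cause == "horizon"
        assert traj.qaly_undiscounted == pytest.approx(expected_q, rel=1e-12)
        assert (traj.records["line_index"] == 0).all()
        assert len(traj.records) == H

    def test_certain_ae_death_in_first_cycle(self, config):
        cfg = config.copy()
        cfg.ae_mortality[rc.ARM_SUNITINIB] = 1.0
        traj = rc.simulate_patient(cfg, rc.ARM_SUNITINIB, seed=5)
        assert traj.terminal_cause == "ae_death"
        assert traj.ly_undiscounted == pytest.approx(cfg.cycle_years)

    def test_single_patient_matches_cohort_of_one(self, config):
        traj = rc.simulate_patient(config, rc.ARM_NIVO_CABO, seed=11)
        res = rc.run_cohort(config, 1, seed=11, arms=(rc.ARM_NIVO_CABO,))
        r = res[rc.ARM_NIVO_CABO]
        assert traj.cost_discounted == pytest.approx(r.mean_cost, rel=1e-12)
        assert traj.qaly_discounted == pytest.approx(r.mean_qaly, rel=1e-12)


class TestCohortInvariants:
    def test_every_patient_ends_dead_or_capped(self, config):
        out = rc.run_cohort(config, 500, seed=7, return_patients=True)
        for arm in rc.ARMS:
            _, res = out[arm]
            assert set(CAUSES[i] for i in res.cause) <= set(CAUSES)
            assert (res.cycles_alive >= 1).all()
            assert (res.cycles_alive <= config.n_cycles()).all()

    def test_discounting_never_increases_accruals(self, config):
        out = rc.run_cohort(config, 500, seed=7, return_patients=True)
        for arm in rc.ARMS:
            _, res = out[arm]
            assert np.all(res.cost <= res.cost_undiscounted + 1e-9)
            assert np.all(res.qaly <= res.qaly_undiscounted + 1e-9)

    def test_utility_monotonicity(self, config):
        base = rc.run_cohort(config, 2_000, seed=13)
        up = set_param(config, "utility.second_line", 0.9)
        better = rc.run_cohort(up, 2_000, seed=13)
        for arm in rc.ARMS:
            assert better[arm].mean_qaly >= base[arm].mean_qaly
            assert better[arm].mean_cost == pytest.approx(base[arm].mean_cost)

    def test_price_rise_only_touches_paying_arm(self, config):
        base = rc.run_cohort(config, 2_000, seed=17)
        pricier = set_param(config, "unit_price.nivolumab", 9_000.0)
        res = rc.run_cohort(pricier, 2_000, seed=17)
        # common random numbers: the sunitinib arm is bit-identical
        assert res[rc.ARM_SUNITINIB].mean_cost == base[rc.ARM_SUNITINIB].mean_cost
        assert res[rc.ARM_SUNITINIB].mean_qaly == base[rc.ARM_SUNITINIB].mean_qaly
        assert res[rc.ARM_NIVO_CABO].mean_cost > base[rc.ARM_NIVO_CABO].mean_cost

    def test_microsim_converges_to_occupancy_expectation(self, config):
        exact = rc.expected_outcomes(config, rc.ARM_SUNITINIB)
        r = rc.run_cohort(config, 40_000, seed=19, arms=(rc.ARM_SUNITINIB,))[
            rc.ARM_SUNITINIB
        ]
        assert r.mean_qaly == pytest.approx(exact["qaly"], rel=0.02)
        assert r.mean_cost == pytest.approx(exact["cost"], rel=0.02)
        assert r.mean_ly == pytest.approx(exact["ly"], rel=0.02)


class TestQuadratureOracles:
    def test_bsc_only_mean_survival_matches_integrated_survival(self, config):
        """With mortality isolated to the BSC overall-survival law, mean
        survival converges to the integral of S (mid-cycle attribution)."""
        cfg = _near_zero_mortality_config(config)
        # instant traversal of the three treatment lines
        for k in cfg.pfs:
            cfg.pfs[k] = rc.ParametricSurvival("loglogistic", 8.0, 1e-6)
        out = rc.run_cohort(
            cfg, 50_000, seed=23, arms=(rc.ARM_SUNITINIB,), return_patients=True
        )
        _, res = out[rc.ARM_SUNITINIB]
        lead_in = 3  # one cycle per treatment line before BSC
        mean_bsc_months = (
            res.cycles_alive.mean() - lead_in - 0.5
        ) * cfg.cycle_months
        horizon_months = (cfg.n_cycles() - lead_in) * cfg.cycle_months
        integral, _ = integrate.quad(
            cfg.bsc_os.survival, 0, horizon_months, limit=300
        )
        assert mean_bsc_months == pytest.approx(integral, rel=0.02)

    def test_time_on_first_line_matches_integrated_pfs(self, config):
        """With discontinuation and death switched off, time on first-line
        therapy converges to the integral of the PFS survival law."""
        cfg = _near_zero_mortality_config(config)
        for k in cfg.discontinuation:
            cfg.discontinuation[k] = 0.0
        # count first-line cycles through the cost channel
        for k in cfg.unit_prices:
            cfg.unit_prices[k] = 0.0
        cfg.unit_prices["sunitinib"] = 1.0 / 28.0  # 1 USD per cycle on line 1
        for k in cfg.ae_management:
            cfg.ae_management[k] = 0.0
        cfg.bsc_cost_per_cycle = 0.0
        cfg.admin_iv_infusion = 0.0
        cfg.discount_rate_annual = 0.0
        r = rc.run_cohort(cfg, 50_000, seed=29, arms=(rc.ARM_SUNITINIB,))[
            rc.ARM_SUNITINIB
        ]
        mean_months = (r.mean_cost - 0.5) * cfg.cycle_months
        integral, _ = integrate.quad(
            cfg.pfs["sunitinib"].survival, 0, cfg.n_cycles() * cfg.cycle_months,
            limit=300,
        )
        assert mean_months == pytest.approx(integral, rel=0.02)


class TestStructure:
    def test_arms_share_second_line_onward(self, config):
        a = build_lines(config, rc.ARM_NIVO_CABO)
        b = build_lines(config, rc.ARM_SUNITINIB)
        assert [ln.name for ln in a] == [
            "nivolumab_cabozantinib", "axitinib", "sorafenib", "bsc"
        ]
        assert a[1:] == b[1:]

    def test_admin_cost_only_on_iv_first_line(self, config):
        a = build_lines(config, rc.ARM_NIVO_CABO)
        b = build_lines(config, rc.ARM_SUNITINIB)
        assert a[0].admin_cost_per_cycle == pytest.approx(3 * 148.3)
        assert b[0].admin_cost_per_cycle == 0.0

    def test_unknown_arm_rejected(self, config):
        with pytest.raises(ValueError):
            build_lines(config, "pembrolizumab")
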