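"""Parametric survival laws: closed forms, fitting, and AIC ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import renalcea as rc
from renalcea.survival import FitResult, make_ipd

LLOG_SUNITINIB = rc.ParametricSurvival("loglogistic", 1.646, 8.269)
LLOG_NIVO_CABO = rc.ParametricSurvival("loglogistic", 1.569, 15.064)


class TestSurvivalFunction:
    def test_starts_at_one_for_every_family(self):
        for fam in rc.FAMILIES:
            m = rc.ParametricSurvival(fam, 1.3, 7.0)
            assert rc.survival_at(m, 0.0) == pytest.approx(1.0)

    def test_loglogistic_median_equals_scale(self):
        assert rc.survival_at(LLOG_SUNITINIB, 8.269) == pytest.approx(0.5, abs=1e-12)
        assert rc.median_survival(LLOG_SUNITINIB) == pytest.approx(8.269)

    def test_loglogistic_closed_form_at_twice_scale(self):
        # independent evaluation of 1 / (1 + 2**shape)
        expected = 1.0 / (1.0 + 2.0**1.569)
        assert rc.survival_at(LLOG_NIVO_CABO, 2 * 15.064) == pytest.approx(
            expected, rel=1e-12
        )

    def test_sunitinib_median_matches_trial_value(self):
        # the fitted sunitinib law should reproduce the trial's 8.3-month
        # median progression-free survival
        assert rc.median_survival(LLOG_SUNITINIB) == pytest.approx(8.3, abs=0.1)

    def test_exponential_median_closed_form(self):
        m = rc.ParametricSurvival.exponential(mean=2.281)
        assert rc.median_survival(m) == pytest.approx(2.281 * np.log(2), rel=1e-12)

    def test_invalid_inputs_raise(self):
        with pytest.raises(ValueError):
            rc.ParametricSurvival("loglogistic", -1.0, 5.0)
        with pytest.raises(ValueError):
            rc.ParametricSurvival("weibull", 1.0, 0.0)
        with pytest.raises(ValueError):
            rc.survival_at(LLOG_SUNITINIB, -1.0)

    @settings(derandomize=True, max_examples=50)
    @given(
        fam=st.sampled_from(rc.FAMILIES),
        shape=st.floats(0.3, 5.0),
        scale=st.floats(0.5, 50.0),
    )
    def test_monotone_nonincreasing_on_grid(self, fam, shape, scale):
        m = rc.ParametricSurvival(fam, shape, scale)
        s = m.survival(np.linspace(0.0, 8 * scale, 1000))
        assert s[0] == pytest.approx(1.0)
        assert np.all(np.diff(s) <= 1e-12)
        assert np.all((s >= 0) & (s <= 1))


class TestTransitionProb:
    def test_exponential_memoryless(self):
        m = rc.ParametricSurvival.exponential(mean=5.0)
        p0 = rc.percycle_transition_prob(m, 0.0, 1.38)
        p10 = rc.percycle_transition_prob(m, 10.0, 1.38)
        assert p0 == pytest.approx(p10, abs=1e-12)

    def test_at_time_zero_equals_one_minus_survival(self):
        p = rc.percycle_transition_prob(LLOG_SUNITINIB, 0.0, 1.38)
        assert p == pytest.approx(1.0 - LLOG_SUNITINIB.survival(1.38), rel=1e-12)

    @pytest.mark.parametrize("fam", rc.FAMILIES)
    def test_small_delta_approaches_hazard(self, fam):
        m = rc.ParametricSurvival(fam, 1.4, 9.0)
        t, eps = 4.0, 1e-5
        # hazard by numerical differentiation of -log S
        h_num = (np.log(m.survival(t)) - np.log(m.survival(t + eps))) / eps
        p = rc.percycle_transition_prob(m, t, eps)
        assert p / eps == pytest.approx(h_num, rel=1e-3)

    @settings(derandomize=True, max_examples=50)
    @given(
        fam=st.sampled_from(rc.FAMILIES),
        shape=st.floats(0.5, 4.0),
        scale=st.floats(1.0, 30.0),
        t=st.floats(0.0, 40.0),
    )
    def test_bounded_in_unit_interval(self, fam, shape, scale, t):
        m = rc.ParametricSurvival(fam, shape, scale)
        p = rc.percycle_transition_prob(m, t, 1.3799)
        assert 0.0 <= p <= 1.0

    def test_invalid_delta_raises(self):
        with pytest.raises(ValueError):
            rc.percycle_transition_prob(LLOG_SUNITINIB, 0.0, 0.0)


class TestFitting:
    def test_uncensored_exponential_matches_closed_form_mle(self):
        rng = np.random.default_rng(7)
        t = rng.exponential(1.0 / 0.2, size=5_000)
        ipd = make_ipd(t, np.ones_like(t))
        fit = rc.fit_parametric(ipd, "exponential")
        # closed-form MLE: mean of the times
        assert fit.model.scale == pytest.approx(t.mean(), rel=1e-6)
        # rate recovered within 3 standard errors (SE = rate / sqrt(n))
        rate = 1.0 / fit.model.scale
        assert abs(rate - 0.2) < 3 * 0.2 / np.sqrt(5_000)

    def test_loglogistic_recovery_under_censoring(self):
        rng = np.random.default_rng(11)
        true = rc.ParametricSurvival("loglogistic", 1.6, 8.3)
        t = true.rvs(5_000, rng)
        # independent uniform censoring yielding ~20% censored records
        c = rng.random(5_000) * 68.96
        obs = np.minimum(t, c)
        ipd = make_ipd(obs, (t <= c).astype(int))
        assert (ipd["event"] == 0).mean() == pytest.approx(0.2, abs=0.03)
        fit = rc.fit_parametric(ipd, "loglogistic")
        assert fit.model.shape == pytest.approx(1.6, rel=0.05)
        assert fit.model.scale == pytest.approx(8.3, rel=0.05)

    def test_agrees_with_lifelines(self):
        lifelines = pytest.importorskip("lifelines")
        rng = np.random.default_rng(3)
        true = rc.ParametricSurvival("loglogistic", 1.5, 10.0)
        t = true.rvs(800, rng)
        event = rng.random(800) > 0.15
        obs = np.where(event, t, t * rng.random(800))
        fit = rc.fit_parametric(make_ipd(obs, event.astype(int)), "loglogistic")
        llf = lifelines.LogLogisticFitter().fit(obs, event)
        assert fit.model.scale == pytest.approx(llf.alpha_, rel=1e-3)
        assert fit.model.shape == pytest.approx(llf.beta_, rel=1e-3)

    def test_degenerate_input_raises(self):
        ipd = make_ipd([1.0, 2.0, 3.0], [1, 0, 0])
        with pytest.raises(ValueError):
            rc.fit_parametric(ipd, "weibull")
        all_censored = make_ipd([1.0, 2.0], [0, 0])
        with pytest.raises(ValueError):
            rc.fit_parametric(all_censored, "exponential")


class TestAicSelect:
    @pytest.fixture(scope="class")
    def exponential_ipd(self):
        rng = np.random.default_rng(5)
        t = rng.exponential(4.0, size=3_000)
        return make_ipd(t, np.ones_like(t))

    def test_exponential_data_ranks_exponential_family_first(self, exponential_ipd):
        ranked = rc.aic_select(exponential_ipd)
        # families nesting the exponential may tie within ~2 AIC; the
        # parsimony tie-break should put the exponential itself on top
        assert ranked[0].model.family in ("exponential", "weibull", "gamma")
        best_aic = ranked[0].aic
        exp_aic = next(f.aic for f in ranked if f.model.family == "exponential")
        assert exp_aic - best_aic < 2.5

    def test_single_family_returned(self, exponential_ipd):
        ranked = rc.aic_select(exponential_ipd, ["weibull"])
        assert len(ranked) == 1 and ranked[0].model.family == "weibull"

    def test_aic_definition(self, exponential_ipd):
        fits = {f.model.family: f for f in rc.aic_select(exponential_ipd)}
        d_ll = fits["weibull"].loglik - fits["exponential"].loglik
        assert fits["weibull"].aic - fits["exponential"].aic == pytest.approx(
            2.0 - 2.0 * d_ll, abs=1e-9
        )

    def test_permutation_invariant(self, exponential_ipd):
        shuffled = exponential_ipd.sample(frac=1.0, random_state=9, ignore_index=True)
        a = [(f.model.family, f.aic) for f in rc.aic_select(exponential_ipd)]
        b = [(f.model.family, f.aic) for f in rc.aic_select(shuffled)]
        for (fam_a, aic_a), (fam_b, aic_b) in zip(a, b):
            assert fam_a == fam_b
            assert aic_a == pytest.approx(aic_b, rel=1e-9)


class TestPooling:
    def test_concatenation_preserves_counts(self):
        a = make_ipd([1.0] * 60 + [2.0] * 40, [1] * 60 + [0] * 40)
        b = make_ipd([3.0] * 150 + [4.0] * 50, [1] * 150 + [0] * 50)
        pooled = rc.pool_ipd(a, b)
        assert len(pooled) == 300
        assert pooled["event"].sum() == a["event"].sum() + b["event"].sum()

    def test_pooled_fit_recovers_common_law(self):
        rng = np.random.default_rng(13)
        true = rc.ParametricSurvival.exponential(mean=2.3)
        a = make_ipd(true.rvs(2_000, rng), np.ones(2_000))
        b = make_ipd(true.rvs(2_000, rng), np.ones(2_000))
        fit = rc.fit_parametric(rc.pool_ipd(a, b), "exponential")
        assert fit.model.scale == pytest.approx(2.3, rel=0.05)

    def test_empty_input_rejected(self):
        a = make_ipd([1.0, 2.0], [1, 1])
        with pytest.raises(ValueError):
            rc.pool_ipd(a, a.iloc[:0])


def test_model_json_round_trip():
    m = rc.ParametricSurvival("weibull", 1.7, 12.5)
    assert rc.ParametricSurvival.from_json(m.to_json()) == m
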