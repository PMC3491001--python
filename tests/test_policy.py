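"""Policy effect sizes, multiplicative combination, schedules."""

import numpy as np
import pytest
import sympy
from hypothesis import given
from hypothesis import strategies as st

from smokesim import (EffectBounds, PolicySchedule, ScheduleError,
                      ValidationError, apply_effects, apply_prevalence_shock,
                      apply_rate_effects, combined_effect, price_effect,
                      schedule_to_effects)
from smokesim.policy import DOMAINS, PolicyEffects, PolicySpec
from smokesim.smoking import N_QUIT_BINS, SmokingState, TransitionRates


def schedule_with(policies, price=None, base_year=1989):
    return PolicySchedule(base_year, price or {base_year: 1.0}, policies)


class TestPriceEffect:
    def test_ten_percent_increase_returns_band_value_exactly(self):
        assert price_effect(1.1, 16) == pytest.approx(0.06, abs=1e-12)
        assert price_effect(1.1, 20) == pytest.approx(0.04, abs=1e-12)
        assert price_effect(1.1, 30) == pytest.approx(0.02, abs=1e-12)
        assert price_effect(1.1, 70) == pytest.approx(0.01, abs=1e-12)

    def test_no_change_no_effect(self):
        for age in (10, 16, 20, 30, 50):
            assert price_effect(1.0, age) == 0.0

    def test_large_increase_against_high_precision_oracle(self):
        # independent evaluation of 1 - 2.3**(ln 0.99 / ln 1.1) at 50 digits
        expected = float(sympy.N(
            1 - sympy.Rational(23, 10)
            ** (sympy.log(sympy.Rational(99, 100)) / sympy.log(sympy.Rational(11, 10))),
            50))
        assert price_effect(2.3, 40) == pytest.approx(expected, abs=1e-12)
        assert price_effect(2.3, 40) == pytest.approx(0.0841, abs=1e-4)

    def test_price_fall_increases_prevalence(self):
        assert price_effect(0.8, 20) < 0

    def test_positive_ratio_required(self):
        with pytest.raises(ValidationError):
            price_effect(0.0, 20)

    def test_under_15_takes_youngest_band(self):
        assert price_effect(1.1, 12) == pytest.approx(0.06, abs=1e-12)


class TestCombinedEffect:
    def test_examples(self):
        assert combined_effect([0.10]) == pytest.approx(0.10)
        assert combined_effect([0.10, 0.05]) == pytest.approx(0.145)
        assert combined_effect([]) == 0.0

    def test_rejects_effect_of_one(self):
        with pytest.raises(ValidationError):
            combined_effect([0.5, 1.0])

    @given(st.lists(st.floats(-0.5, 0.99), max_size=8))
    def test_commutative_and_bounded(self, effects):
        forward = combined_effect(effects)
        backward = combined_effect(list(reversed(effects)))
        assert forward == pytest.approx(backward, rel=1e-12, abs=1e-12)
        assert forward < 1.0
        if all(e >= 0 for e in effects):
            assert 0.0 <= forward

    @given(st.lists(st.floats(0, 0.9), min_size=2, max_size=6))
    def test_associative_under_composition(self, effects):
        combined = combined_effect(effects)
        nested = combined_effect([effects[0], combined_effect(effects[1:])])
        assert combined == pytest.approx(nested, rel=1e-12, abs=1e-12)


class TestScheduleToEffects:
    def test_base_levels_give_zero(self):
        sched = schedule_with({1989: {"marketing": {"level": "weak"}}})
        eff = schedule_to_effects(sched, 2005)
        assert np.all(eff.prevalence == 0)
        assert np.all(eff.initiation == 0)
        assert np.all(eff.cessation == 0)

    def test_media_doubling_with_other_policies(self):
        alone = schedule_with({2000: {"media": {"level": "high"}}})
        eff = schedule_to_effects(alone, 2000)
        assert eff.prevalence[40] == pytest.approx(0.0325)
        with_other = schedule_with({2000: {"media": {"level": "high"},
                                           "warnings": {"level": "weak"}}})
        eff2 = schedule_to_effects(with_other, 2000)
        media_part = 1 - (1 - eff2.prevalence[40]) / (1 - 0.01)
        assert media_part == pytest.approx(0.065, rel=1e-9)

    def test_strong_warnings_triplet(self):
        sched = schedule_with({2001: {"warnings": {"level": "strong"}}})
        eff = schedule_to_effects(sched, 2001)
        assert eff.prevalence[40] == pytest.approx(0.04)
        assert eff.initiation[20] == pytest.approx(0.04)
        assert eff.cessation[40] == pytest.approx(0.10)

    def test_smokefree_components_additive(self):
        sched = schedule_with({2000: {"smokefree": {
            "components": {"worksite": 1.0, "restaurant": 1.0, "bar": 1.0,
                           "other": 1.0}, "enforcement": 1.0}}})
        eff = schedule_to_effects(sched, 2000)
        assert eff.prevalence[40] == pytest.approx(0.09 + 0.03 + 0.015 + 0.01)

    def test_enforcement_halves_effect_at_zero_score(self):
        full = schedule_with({2000: {"marketing": {"level": "comprehensive",
                                                   "enforcement": 1.0}}})
        none = schedule_with({2000: {"marketing": {"level": "comprehensive",
                                                   "enforcement": 0.0}}})
        e_full = schedule_to_effects(full, 2000).prevalence[40]
        e_none = schedule_to_effects(none, 2000).prevalence[40]
        assert e_full == pytest.approx(0.10)
        assert e_none == pytest.approx(0.05)

    def test_incrementality_over_base_level(self):
        """A domain already at a partial level contributes only the
        renormalised increment of the stronger level."""
        sched = schedule_with({1989: {"marketing": {"level": "weak"}},
                               2000: {"marketing": {"level": "comprehensive"}}})
        eff = schedule_to_effects(sched, 2000)
        expected = 1 - (1 - 0.10) / (1 - 0.02)
        assert eff.prevalence[40] == pytest.approx(expected)
        # unchanged level contributes zero
        assert schedule_to_effects(sched, 1995).prevalence[40] == 0.0

    def test_youth_access_under_18_only(self):
        sched = schedule_with({2000: {"youth_access": {"level": "strong"}}})
        eff = schedule_to_effects(sched, 2000)
        assert eff.prevalence[14] == pytest.approx(0.30)
        assert eff.prevalence[16] == pytest.approx(0.20)
        assert eff.prevalence[18] == 0.0
        assert np.all(eff.cessation == 0)

    def test_cessation_treatment_levels(self):
        sched = schedule_with({2000: {"cessation_treatment": {"level": "complete"}}})
        eff = schedule_to_effects(sched, 2000)
        assert eff.cessation[40] == pytest.approx(0.55)
        assert eff.prevalence[40] == pytest.approx(0.0675)

    def test_bound_variants_scale_effects(self):
        sched = schedule_with({2000: {"warnings": {"level": "strong"}}})
        lo = schedule_to_effects(sched, 2000, bound="lower").prevalence[40]
        mid = schedule_to_effects(sched, 2000, bound="central").prevalence[40]
        hi = schedule_to_effects(sched, 2000, bound="upper").prevalence[40]
        assert lo == pytest.approx(0.02)
        assert mid == pytest.approx(0.04)
        assert hi == pytest.approx(0.06)

    def test_unknown_level_label_rejected(self):
        with pytest.raises(ScheduleError):
            schedule_with({2000: {"warnings": {"level": "gigantic"}}})
        with pytest.raises(ScheduleError):
            PolicySpec("nonsense_domain")


class TestApplyEffects:
    def _state(self):
        s = SmokingState(np.zeros((45, 2)), np.zeros((45, 2)),
                         np.zeros((45, 2, N_QUIT_BINS)))
        s.current[40] = 1000.0
        return s

    def test_prevalence_shock_moves_smokers_to_quit_bin(self):
        eff = np.zeros(45)
        eff[40] = 0.10
        out = apply_prevalence_shock(self._state(), eff)
        assert out.current[40, 0] == pytest.approx(900.0)
        assert out.former[40, 0, 0] == pytest.approx(100.0)

    def test_cessation_multiplier(self):
        cess = np.zeros((45, 2))
        cess[30:] = 0.05
        rates = TransitionRates(np.zeros((45, 2)), cess, np.zeros(N_QUIT_BINS))
        eff = PolicyEffects.zero(45)
        eff.cessation[:] = 0.55
        out = apply_rate_effects(rates, eff)
        assert out.cessation[40, 0] == pytest.approx(0.0775)

    def test_zero_effects_identity(self):
        state = self._state()
        cess = np.zeros((45, 2))
        cess[30:] = 0.05
        rates = TransitionRates(np.zeros((45, 2)), cess, np.zeros(N_QUIT_BINS))
        out_state, out_rates = apply_effects(state, rates, PolicyEffects.zero(45))
        np.testing.assert_array_equal(out_state.current, state.current)
        np.testing.assert_array_equal(out_rates.cessation, rates.cessation)

    def test_sustained_level_no_second_shock(self):
        eff = np.zeros(45)
        eff[40] = 0.10
        once = apply_prevalence_shock(self._state(), eff)
        again = apply_prevalence_shock(once, eff, effect_prior=eff)
        np.testing.assert_array_equal(again.current, once.current)

    def test_weakening_effect_returns_recent_quitters(self):
        eff = np.zeros(45)
        eff[40] = 0.10
        shocked = apply_prevalence_shock(self._state(), eff)
        relaxed = apply_prevalence_shock(shocked, np.zeros(45), effect_prior=eff)
        assert relaxed.current[40, 0] == pytest.approx(1000.0)
        assert relaxed.former[40, 0, 0] == pytest.approx(0.0)


def test_effect_bounds_validation():
    with pytest.raises(ValidationError):
        EffectBounds({"price": (1.2, 1.5)})
    b = EffectBounds()
    assert b.multiplier("youth_access", "lower") == 0.0
    assert b.multiplier("cessation_treatment", "upper") == 2.0
    with pytest.raises(ValidationError):
        b.multiplier("price", "sideways")


class TestPolicySchedule:
    def test_price_interpolation_and_flat_extension(self):
        sched = PolicySchedule(1989, {1989: 1.0, 1998: 2.0, 2010: 2.3}, {})
        assert sched.price_ratio(1989) == 1.0
        assert sched.price_ratio(1998) == 2.0
        assert sched.price_ratio(1993.5) == pytest.approx(1.5)
        assert sched.price_ratio(2010) == pytest.approx(2.3)
        assert sched.price_ratio(2040) == pytest.approx(2.3)

    def test_forward_fill_of_levels(self):
        sched = schedule_with({1996: {"warnings": {"level": "weak"}},
                               2001: {"warnings": {"level": "strong"}}})
        assert sched.spec("warnings", 1990).level is None
        assert sched.spec("warnings", 1999).level == "weak"
        assert sched.spec("warnings", 2030).level == "strong"

    def test_frozen_and_single_domain(self):
        sched = schedule_with({1996: {"warnings": {"level": "weak"}},
                               2000: {"media": {"level": "high"}}},
                              price={1989: 1.0, 2000: 2.0})
        frozen = sched.frozen_at(1989)
        assert frozen.spec("warnings", 2010).level is None
        assert frozen.price_ratio(2010) == 1.0
        only_warn = sched.single_domain("warnings")
        assert only_warn.spec("warnings", 2005).level == "weak"
        assert only_warn.spec("media", 2005).level is None
        assert only_warn.price_ratio(2005) == 1.0
        only_price = sched.single_domain("price")
        assert only_price.price_ratio(2000) == pytest.approx(2.0)
        assert only_price.spec("warnings", 2005).level is None

    def test_roundtrip_dict(self):
        sched = schedule_with({1996: {"smokefree": {
            "components": {"worksite": 0.5}, "enforcement": 0.7}}},
            price={1989: 1.0, 2000: 2.0})
        again = PolicySchedule.from_dict(sched.to_dict())
        assert again == sched
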