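"""Consumption shift model, wellbeing proxy and elasticity scenario."""

from __future__ import annotations

from collections import defaultdict

import pytest
from hypothesis import given, settings, strategies as st

from cannabis_cba import (
    IntentDistribution,
    UseCategory,
    elasticity_scenario,
    prevalence_change,
    shift_profile,
    wellbeing_value,
)
from cannabis_cba.consumption import USER_CATEGORIES

from conftest import make_profile


def intents(increase=0.0, try_it=0.0, decrease=0.0, not_use=0.0):
    return IntentDistribution(
        users={
            "not_use": not_use,
            "decrease": decrease,
            "increase": increase,
            "no_change": 1.0 - increase - decrease - not_use,
        },
        non_users={"try_it": try_it, "not_use": 1.0 - try_it},
    )


def oracle_shift(profile, intent_dist):
    """Per-person expectation loop: the hand-enumeration oracle."""
    new = defaultdict(float)
    users = profile.n_users
    shares = profile.user_shares() if users > 0 else {}
    p_inc = intent_dist.users["increase"]
    p_try = intent_dist.non_users["try_it"]
    for cat, n in profile.counts.items():
        for _ in range(int(round(n))):
            if cat is UseCategory.NONE:
                new[UseCategory.NONE] += 1.0 - p_try
                for user_cat, share in shares.items():
                    new[user_cat] += p_try * share
            else:
                new[cat] += 1.0 - p_inc
                new[cat.shifted_up()] += p_inc
    return new


class TestShiftProfile:
    def test_monthly_increasers_become_weekly(self):
        profile = make_profile({UseCategory.MONTHLY: 100.0})
        shifted = shift_profile(profile, intents(increase=1.0))
        assert shifted.counts[UseCategory.AT_LEAST_WEEKLY] == pytest.approx(100.0)
        assert shifted.counts[UseCategory.MONTHLY] == pytest.approx(0.0)

    def test_daily_saturates(self):
        profile = make_profile({UseCategory.DAILY: 50.0})
        shifted = shift_profile(profile, intents(increase=1.0))
        assert shifted.counts[UseCategory.DAILY] == pytest.approx(50.0)

    def test_no_change_is_identity(self):
        profile = make_profile(
            {UseCategory.NONE: 900.0, UseCategory.MONTHLY: 60.0, UseCategory.DAILY: 40.0}
        )
        shifted = shift_profile(profile, intents())
        for cat in UseCategory:
            assert shifted.counts.get(cat, 0.0) == pytest.approx(
                profile.counts.get(cat, 0.0)
            )

    def test_triers_allocated_proportionally(self):
        # 10 triers against user shares (0.5, 0.3, 0.2) -> (5, 3, 2)
        profile = make_profile(
            {
                UseCategory.NONE: 100.0,
                UseCategory.LESS_THAN_MONTHLY: 50.0,
                UseCategory.MONTHLY: 30.0,
                UseCategory.AT_LEAST_WEEKLY: 20.0,
            }
        )
        shifted = shift_profile(profile, intents(try_it=0.1))
        assert shifted.counts[UseCategory.LESS_THAN_MONTHLY] == pytest.approx(55.0)
        assert shifted.counts[UseCategory.MONTHLY] == pytest.approx(33.0)
        assert shifted.counts[UseCategory.AT_LEAST_WEEKLY] == pytest.approx(22.0)
        assert shifted.counts[UseCategory.NONE] == pytest.approx(90.0)

    def test_negative_intent_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            intents(increase=-0.1)

    def test_decreaser_switch_moves_down_and_out(self):
        profile = make_profile({UseCategory.MONTHLY: 100.0})
        shifted = shift_profile(
            profile, intents(decrease=0.3, not_use=0.1), shift_decreasers=True
        )
        assert shifted.counts[UseCategory.LESS_THAN_MONTHLY] == pytest.approx(30.0)
        assert shifted.counts[UseCategory.NONE] == pytest.approx(10.0)
        assert shifted.counts[UseCategory.MONTHLY] == pytest.approx(60.0)

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=6), min_size=5, max_size=5),
        p_inc=st.floats(0.0, 1.0),
        p_try=st.floats(0.0, 1.0),
    )
    def test_matches_hand_enumeration_oracle(self, counts, p_inc, p_try):
        """On populations of <= 20 (and a bit above) the vectorised shift
        equals the per-person expectation loop, and population is conserved
        exactly."""
        count_map = {cat: float(n) for cat, n in zip(UseCategory, counts)}
        if sum(count_map[c] for c in USER_CATEGORIES) == 0:
            p_try = 0.0  # no use pattern for triers to copy
        profile = make_profile(count_map)
        intent_dist = intents(increase=p_inc, try_it=p_try)
        shifted = shift_profile(profile, intent_dist)
        expected = oracle_shift(profile, intent_dist)
        for cat in UseCategory:
            assert shifted.counts.get(cat, 0.0) == pytest.approx(
                expected.get(cat, 0.0), abs=1e-9
            )
        assert shifted.population == pytest.approx(profile.population, abs=1e-9)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(p_inc=st.floats(0.0, 1.0), p_try=st.floats(0.0, 1.0))
    def test_consumption_never_decreases_without_decreasers(self, p_inc, p_try):
        profile = make_profile(
            {
                UseCategory.NONE: 500.0,
                UseCategory.LESS_THAN_MONTHLY: 23.0,
                UseCategory.MONTHLY: 8.5,
                UseCategory.AT_LEAST_WEEKLY: 11.0,
                UseCategory.DAILY: 7.5,
            }
        )
        shifted = shift_profile(profile, intents(increase=p_inc, try_it=p_try))
        assert shifted.total_grams >= profile.total_grams - 1e-9


class TestPrevalenceChange:
    def test_identity_shift(self):
        profile = make_profile({UseCategory.NONE: 90.0, UseCategory.DAILY: 10.0})
        change = prevalence_change(profile, profile)
        assert change.relative_prevalence_change == 0.0
        assert change.new_population_rate == pytest.approx(0.1)
        assert change.relative_consumption_change == 0.0

    def test_doubling_users_doubles_consumption(self):
        base = make_profile(
            {UseCategory.NONE: 180.0, UseCategory.MONTHLY: 12.0, UseCategory.DAILY: 8.0}
        )
        doubled = make_profile(
            {UseCategory.NONE: 160.0, UseCategory.MONTHLY: 24.0, UseCategory.DAILY: 16.0}
        )
        change = prevalence_change(base, doubled)
        assert change.relative_consumption_change == pytest.approx(1.0)
        assert change.relative_prevalence_change == pytest.approx(1.0)

    def test_zero_population_rejected(self):
        empty = make_profile({UseCategory.NONE: 0.0})
        with pytest.raises(ValueError, match="zero population"):
            prevalence_change(empty, empty)

    def test_default_calibration_reproduces_headline_shift(self, config):
        """Packaged intents: prevalence +44% to 12.4%, consumption +55%."""
        from cannabis_cba import consumption_shift

        change = consumption_shift(config).change
        assert change.relative_prevalence_change == pytest.approx(0.44, abs=1e-9)
        assert change.new_population_rate == pytest.approx(0.124, abs=5e-4)
        assert change.relative_consumption_change == pytest.approx(0.55, abs=1e-9)


class TestWellbeing:
    def test_million_grams_at_twenty_dollars(self):
        profile = make_profile(
            {UseCategory.DAILY: 1_000_000.0 / 365.0},
            grams_per_use_day={UseCategory.DAILY: 1.0},
            use_days={UseCategory.DAILY: 365.0},
        )
        assert wellbeing_value(profile, 20.0) == pytest.approx(20.0)

    def test_full_exclusion_gives_zero(self):
        profile = make_profile({UseCategory.DAILY: 10.0})
        assert wellbeing_value(profile, 20.0, profile.total_grams) == 0.0

    def test_excluding_more_than_total_rejected(self):
        profile = make_profile({UseCategory.DAILY: 1.0})
        with pytest.raises(ValueError, match="excluded_grams"):
            wellbeing_value(profile, 20.0, profile.total_grams + 1.0)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(scale=st.floats(0.1, 10.0), price=st.floats(0.5, 100.0))
    def test_homogeneous_in_price_and_quantity(self, scale, price):
        base = make_profile({UseCategory.AT_LEAST_WEEKLY: 100.0})
        scaled = make_profile({UseCategory.AT_LEAST_WEEKLY: 100.0 * scale})
        v = wellbeing_value(base, price)
        assert wellbeing_value(scaled, price) == pytest.approx(scale * v)
        assert wellbeing_value(base, price * scale) == pytest.approx(scale * v)

    def test_default_calibration_reproduces_table_rows(self, config):
        from cannabis_cba import consumption_shift

        shift = consumption_shift(config)
        price = config.price_per_gram
        for policy, profile, expected in (
            ("status_quo", shift.baseline, 579.1),
            ("legalised_regulated", shift.shifted, 645.5),
        ):
            excluded = config.excluded_share(policy) * profile.total_grams
            assert wellbeing_value(profile, price, excluded) == pytest.approx(
                expected, abs=1e-6
            )


class TestElasticityScenario:
    @pytest.mark.parametrize(
        "price_change,expected",
        [(-0.5, 806.875), (+0.5, 484.125)],
    )
    def test_published_scenarios(self, price_change, expected):
        assert elasticity_scenario(645.5, price_change, 0.5) == pytest.approx(expected)

    def test_zero_elasticity_is_identity(self):
        assert elasticity_scenario(123.4, -0.9, 0.0) == 123.4

    def test_converges_to_base_as_price_change_vanishes(self):
        for eps in (1e-2, 1e-4, 1e-6):
            assert elasticity_scenario(100.0, -eps, 0.5) == pytest.approx(100.0, abs=100.0 * eps)
        assert elasticity_scenario(100.0, 0.0, 0.5) == 100.0

    def test_negative_quantity_rejected(self):
        with pytest.raises(ValueError, match="negative quantity"):
            elasticity_scenario(100.0, +0.9, 2.0)

    def test_negative_elasticity_rejected(self):
        with pytest.raises(ValueError, match="elasticity"):
            elasticity_scenario(100.0, -0.5, -0.1)
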