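"""NSB aggregation, Monte Carlo propagation and scenario runner."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import stats

from cannabis_cba import (
    Category,
    ComponentEstimate,
    Flow,
    Ledger,
    MonteCarloConfig,
    Policy,
    ScenarioSpec,
    apply_scenario,
    one_way_sensitivity,
    point_nsb,
    point_scenario_nsb,
    run_monte_carlo,
    run_scenario,
    sample_component,
)
from cannabis_cba.nsb import Z90, component_normal


def make(name, flow, main, low=None, high=None, policy=Policy.STATUS_QUO, include=True):
    low = main if low is None else low
    high = main if high is None else high
    return ComponentEstimate(
        name=name,
        policy=policy,
        category=Category.OTHER_AGENCIES,
        flow=flow,
        main=main,
        low=low,
        high=high,
        include_in_nsb=include,
    )


class TestPointNSB:
    def test_status_quo_fixture(self, sq_ledger):
        assert point_nsb(sq_ledger, "status_quo") == pytest.approx(282.6)

    def test_empty_ledger(self):
        assert point_nsb(Ledger(()), "status_quo") == 0.0

    def test_revenue_adds_net_revenue(self, lr_ledger):
        without = point_nsb(lr_ledger, "legalised_regulated")
        with_revenue = point_nsb(lr_ledger, "legalised_regulated", include_revenue=True)
        assert without == pytest.approx(317.75 - 90.8)
        assert with_revenue - without == pytest.approx(1360.0 - 617.5 - 82.86)

    def test_policy_without_components_rejected(self, sq_ledger):
        with pytest.raises(ValueError, match="no components"):
            point_nsb(sq_ledger, "legalised_regulated")


class TestSampling:
    def test_degenerate_range_returns_main_exactly(self):
        flat = make("flat", Flow.COST, 5.0)
        rng = np.random.default_rng(0)
        config = MonteCarloConfig(seed=0)
        assert all(sample_component(flat, config, rng) == 5.0 for _ in range(10))

    @pytest.mark.parametrize(
        "low,high,expected_sd",
        [(83.55, 116.45, 10.0), (20.2, 33.7, 4.10)],
    )
    def test_sd_reads_range_as_central_90_interval(self, low, high, expected_sd):
        component = make("c", Flow.BENEFIT, (low + high) / 2, low, high)
        _, sd = component_normal(component)
        assert sd == pytest.approx(expected_sd, abs=5e-3)

    def test_sd_rule_choices_differ_only_in_mean(self):
        component = make("c", Flow.COST, 27.0, 20.2, 33.7)
        mean_c, sd_c = component_normal(component, "central90")
        mean_m, sd_m = component_normal(component, "main")
        assert sd_c == sd_m
        assert mean_c == pytest.approx(26.95)
        assert mean_m == 27.0

    def test_empirical_sd_matches_formula(self):
        component = make("c", Flow.BENEFIT, 100.0, 83.55, 116.45)
        rng = np.random.default_rng(42)
        config = MonteCarloConfig(seed=42)
        draws = np.array([sample_component(component, config, rng) for _ in range(10_000)])
        se = 10.0 / np.sqrt(2 * (10_000 - 1))
        assert draws.std(ddof=1) == pytest.approx(10.0, abs=3 * se)


class TestMonteCarlo:
    def test_degenerate_ledger_equals_point_nsb_any_seed(self):
        ledger = Ledger(
            (make("b", Flow.BENEFIT, 100.0), make("c", Flow.COST, 30.0), make("d", Flow.DISBENEFIT, 15.0))
        )
        for seed in (0, 1, 12345):
            result = run_monte_carlo(ledger, "status_quo", MonteCarloConfig(seed=seed))
            assert result.mean == point_nsb(ledger, "status_quo") == 55.0
            assert result.p5 == result.p95 == result.mean
            assert np.all(result.draws == 55.0)

    def test_single_normal_component_percentiles(self):
        ledger = Ledger((make("b", Flow.BENEFIT, 100.0, 83.55, 116.45),))
        config = MonteCarloConfig(repetitions=10_000, seed=7)
        result = run_monte_carlo(ledger, "status_quo", config)
        # closed form: Normal(100, 10); 4 SE tolerance at 10k reps
        se_mean = 10.0 / np.sqrt(10_000)
        q_se = 10.0 * np.sqrt(0.05 * 0.95 / 10_000) / stats.norm.pdf(Z90)
        assert result.mean == pytest.approx(100.0, abs=4 * se_mean)
        assert result.p5 == pytest.approx(83.55, abs=4 * q_se)
        assert result.p95 == pytest.approx(116.45, abs=4 * q_se)

    def test_matches_closed_form_normal_sum_oracle(self, sq_ledger):
        """NSB draws are a signed sum of independent normals, so the mean
        and both percentiles must match Normal(sum signed means, sqrt(sum
        sd^2)) within 4 standard errors at 10,000 repetitions."""
        config = MonteCarloConfig(repetitions=10_000, seed=123)
        result = run_monte_carlo(sq_ledger, "status_quo", config)
        mus, variances = [], []
        for c in sq_ledger.filter(policy="status_quo"):
            if not c.include_in_nsb:
                continue
            mu, sd = component_normal(c, config.sd_rule)
            mus.append(c.nsb_sign * mu)
            variances.append(sd**2)
        mean = sum(mus)
        sd = float(np.sqrt(sum(variances)))
        n = config.repetitions
        se_mean = sd / np.sqrt(n)
        q_se = sd * np.sqrt(0.05 * 0.95 / n) / stats.norm.pdf(Z90)
        assert result.mean == pytest.approx(mean, abs=4 * se_mean)
        assert result.p5 == pytest.approx(mean - Z90 * sd, abs=4 * q_se)
        assert result.p95 == pytest.approx(mean + Z90 * sd, abs=4 * q_se)

    def test_seed_reproducibility_bit_exact(self, lr_ledger):
        config = MonteCarloConfig(seed=99)
        a = run_monte_carlo(lr_ledger, "legalised_regulated", config, include_revenue=True)
        b = run_monte_carlo(lr_ledger, "legalised_regulated", config, include_revenue=True)
        assert np.array_equal(a.draws, b.draws)
        assert (a.mean, a.p5, a.p95) == (b.mean, b.p5, b.p95)

    def test_truncation_clips_component_draws(self):
        ledger = Ledger((make("c", Flow.COST, 1.0, 0.0, 2.0),))
        config = MonteCarloConfig(repetitions=2_000, seed=3, truncate_at_zero=True)
        result = run_monte_carlo(ledger, "status_quo", config)
        assert np.all(result.draws <= 0.0)  # costs enter negatively
        untruncated = run_monte_carlo(
            ledger, "status_quo", MonteCarloConfig(repetitions=2_000, seed=3)
        )
        assert untruncated.draws.max() > 0.0  # sanity: clipping did something

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            MonteCarloConfig(repetitions=0)
        with pytest.raises(ValueError):
            MonteCarloConfig(percentiles=(95.0, 5.0))
        with pytest.raises(ValueError):
            MonteCarloConfig(sd_rule="triangular")


class TestScenarios:
    def test_identity_scenario_equals_plain_run_draw_for_draw(self, sq_ledger):
        config = MonteCarloConfig(seed=11)
        plain = run_monte_carlo(sq_ledger, "status_quo", config)
        scenario = run_scenario(sq_ledger, "status_quo", ScenarioSpec(), config)
        assert np.array_equal(plain.draws, scenario.draws)

    def test_halving_wellbeing_turns_both_policies_negative(self, sq_ledger, lr_ledger):
        spec = ScenarioSpec(component_scalings={"wellbeing": 0.5})
        sq = point_scenario_nsb(sq_ledger, "status_quo", spec)
        lr = point_scenario_nsb(lr_ledger, "legalised_regulated", spec)
        assert sq == pytest.approx(282.6 - 579.1 / 2)  # -6.95
        assert sq < 0.0
        assert lr < 0.0

    def test_removing_education_raises_nsb_by_its_main(self, sq_ledger):
        spec = ScenarioSpec(component_scalings={"education_attainment": 0.0})
        base = point_nsb(sq_ledger, "status_quo")
        assert point_scenario_nsb(sq_ledger, "status_quo", spec) == pytest.approx(
            base + 197.3
        )

    def test_removing_wellbeing_and_education_keeps_nsb_negative(
        self, sq_ledger, lr_ledger
    ):
        spec = ScenarioSpec(component_scalings={"wellbeing": 0.0, "education_attainment": 0.0})
        assert point_scenario_nsb(sq_ledger, "status_quo", spec) < 0.0
        assert point_scenario_nsb(lr_ledger, "legalised_regulated", spec) < 0.0

    def test_unknown_component_error_lists_valid_names(self, sq_ledger):
        with pytest.raises(KeyError, match="wellbeing"):
            apply_scenario(sq_ledger, ScenarioSpec(component_scalings={"wellbieng": 0.5}))

    def test_point_override_uses_bound(self, sq_ledger):
        spec = ScenarioSpec(point_overrides={"penalties_corrections": "use_low"})
        modified = apply_scenario(sq_ledger, spec)
        assert modified.get("penalties_corrections").main == 20.2

    def test_elasticity_spec_scales_wellbeing(self, lr_ledger):
        spec = ScenarioSpec(elasticity=(-0.5, 0.5))
        modified = apply_scenario(lr_ledger, spec)
        assert modified.get("wellbeing").main == pytest.approx(806.875)

    def test_scaling_cost_upward_never_raises_nsb(self, sq_ledger):
        base = point_nsb(sq_ledger, "status_quo")
        for factor in (1.1, 2.0, 5.0):
            spec = ScenarioSpec(component_scalings={"police": factor})
            assert point_scenario_nsb(sq_ledger, "status_quo", spec) <= base

    def test_negative_scaling_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ScenarioSpec(component_scalings={"wellbeing": -1.0})


class TestOneWaySweep:
    def test_shape_and_base_consistency(self, sq_ledger):
        frame = one_way_sensitivity(sq_ledger, "status_quo")
        included = [c for c in sq_ledger if c.include_in_nsb]
        assert len(frame) == 2 * len(included)
        # replacing a cost main by its low bound raises the NSB
        row = frame[(frame.component == "penalties_corrections") & (frame.bound == "low")]
        assert float(row.delta_nsb.iloc[0]) == pytest.approx(27.0 - 20.2)
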