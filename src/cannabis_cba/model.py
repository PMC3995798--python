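"""End-to-end deterministic pipeline: config -> modelled components.

This module strings the sub-models together in expectation (no sampling):
the intent question shifts the baseline consumption profile, the shifted
and baseline profiles feed the harm calculators and the wellbeing proxy,
and the market model produces the supply-side components.  Each modelled
value is returned beside its ledger row so the fixture acts as an
independent check on the calculators rather than their source.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import harms
from .config import AnalysisConfig, default_config
from .consumption import (
    ConsumptionProfile,
    PrevalenceShift,
    prevalence_change,
    shift_profile,
    wellbeing_value,
)
from .ledger import Ledger, load_legalised_regulated, load_status_quo
from .market import (
    grower_greenhouse_receipts,
    legalised_public_costs,
    licence_cost,
    retail_operating_cost,
    revenue_statement,
)

__all__ = ["ShiftSummary", "consumption_shift", "modelled_components", "market_summary"]


@dataclass(frozen=True)
class ShiftSummary:
    baseline: ConsumptionProfile
    shifted: ConsumptionProfile
    change: PrevalenceShift


def consumption_shift(config: AnalysisConfig | None = None) -> ShiftSummary:
    """Baseline and legalisation profiles with the headline shift statistics."""
    config = config or default_config()
    baseline = config.baseline_profile()
    shifted = shift_profile(baseline, config.intents(), config.shift_decreasers)
    return ShiftSummary(baseline, shifted, prevalence_change(baseline, shifted))


def modelled_components(config: AnalysisConfig | None = None) -> pd.DataFrame:
    """Recompute every modelled ledger component from the configuration.

    Returns one row per (component, policy) with the modelled value and
    the packaged fixture's (main, low, high) for comparison, all in
    millions of 2007 AUD.  Components the model takes as given (criminal
    justice costings from administrative data, low-birth-weight care,
    etc.) are not rows here.
    """
    config = config or default_config()
    params = config.harm_parameters()
    shift = consumption_shift(config)
    baseline, shifted = shift.baseline, shift.shifted

    rows: list[dict] = []

    def add(name: str, policy: str, value: float) -> None:
        rows.append({"component": name, "policy": policy, "modelled": value})

    # wellbeing proxy, per policy
    price = config.price_per_gram
    for policy, profile in (
        ("status_quo", baseline),
        ("legalised_regulated", shifted),
    ):
        excluded = config.excluded_share(policy) * profile.total_grams
        add("wellbeing", policy, wellbeing_value(profile, price, excluded))

    # psychosis / schizophrenia: status-quo row taken as given, the
    # legalised row adds NNP-derived incident cases
    delta = harms.delta_users_by_stratum(baseline, shifted)
    burden = harms.attributable_case_burden(delta, params)
    additional = sum(b.cost_millions for b in burden.values())
    add("schizophrenia_psychosis", "status_quo", config.status_quo_mental_health_cost)
    add(
        "schizophrenia_psychosis",
        "legalised_regulated",
        config.status_quo_mental_health_cost + additional,
    )

    # CUD treatment
    eligible_sq, eligible_lr = harms.cud_eligible_users(
        baseline, shifted, params.cud_first_year_factor
    )
    add(
        "treatment_cud",
        "status_quo",
        harms.cud_treatment_cost(
            eligible_sq, params.cud_rate, params.treatment_cost_per_case["status_quo"]
        ),
    )
    add(
        "treatment_cud",
        "legalised_regulated",
        harms.cud_treatment_cost(
            eligible_lr,
            params.cud_rate,
            params.treatment_cost_per_case["legalised_regulated"],
        ),
    )

    # road accidents: mortality valuation and health-system costs, as levels
    for policy, profile in (
        ("status_quo", baseline),
        ("legalised_regulated", shifted),
    ):
        accident = harms.accident_burden(profile.total_use_days, params)
        add("vosly_accidents", policy, accident.mortality_value_millions)
        add("motor_vehicle_accidents", policy, accident.injury_cost_millions)

    # education attainment
    for policy in ("status_quo", "legalised_regulated"):
        add(
            "education_attainment",
            policy,
            harms.education_loss(
                params.affected_education[policy],
                params.years_lost_per_affected,
                params.average_earnings,
                params.earnings_share_per_school_year,
            ),
        )

    # status-quo criminal-record components
    add(
        "lost_wages_incarcerated",
        "status_quo",
        harms.incarceration_wage_loss(
            params.incarcerated_by_offence,
            params.mean_sentence_years,
            params.minimum_wage_2007,
        ),
    )
    add("stigma", "status_quo", harms.stigma_value(params.n_new_convictions, params.stigma_wtp))

    # legalised-regulated supply side
    market = config.market_parameters()
    add("personal_licence", "legalised_regulated", licence_cost(market.n_licensed, market.licence_fee))
    operating = retail_operating_cost(market)
    add("operating_shops", "legalised_regulated", operating)
    statement = revenue_statement(
        market.total_grams_sold,
        market.retail_price_per_gram,
        market.grower_price_per_gram,
        operating,
        market.leakage,
        market.leakage_on_grower,
    )
    add("gross_revenue", "legalised_regulated", statement.gross_millions)
    add("payments_to_growers", "legalised_regulated", statement.grower_payments_millions)
    public = legalised_public_costs(market)
    add("regulatory_agency", "legalised_regulated", public["regulator"])
    add("enforcing_regulations", "legalised_regulated", public["enforcement"])
    add("consumer_information_quit", "legalised_regulated", public["info_quit"])

    frame = pd.DataFrame(rows)
    fixtures = {
        "status_quo": load_status_quo(),
        "legalised_regulated": load_legalised_regulated(),
    }

    def lookup(row: pd.Series, field: str) -> float:
        ledger: Ledger = fixtures[row["policy"]]
        return getattr(ledger.get(row["component"]), field)

    for field in ("main", "low", "high"):
        frame[f"table_{field}"] = frame.apply(lookup, axis=1, args=(field,))
    return frame


def market_summary(config: AnalysisConfig | None = None) -> dict:
    """Revenue statement plus supporting quantities, for reporting."""
    config = config or default_config()
    market = config.market_parameters()
    operating = retail_operating_cost(market)
    statement = revenue_statement(
        market.total_grams_sold,
        market.retail_price_per_gram,
        market.grower_price_per_gram,
        operating,
        market.leakage,
        market.leakage_on_grower,
    )
    lo, hi = market.grower_price_range
    return {
        "statement": statement,
        "public_costs": legalised_public_costs(market),
        "licence_cost_millions": licence_cost(market.n_licensed, market.licence_fee),
        "greenhouse_receipts_range_millions": (
            grower_greenhouse_receipts(lo, market.greenhouse_yield_grams),
            grower_greenhouse_receipts(hi, market.greenhouse_yield_grams),
        ),
    }
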