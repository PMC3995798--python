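"""Structured model configuration.

All externally sourced coefficients — survey-derived use patterns, street
price, harm coefficients, supply-side parameters and Monte Carlo settings —
live in one YAML document.  The packaged default
(``data/default_config.yaml``) documents, entry by entry, which values are
back-solved calibrations and which published aggregate each reproduces.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .consumption import ConsumptionProfile, IntentDistribution, UseCategory
from .harms import HarmParameters
from .market import MarketParameters
from .nsb import MonteCarloConfig

__all__ = [
    "AnalysisConfig",
    "load_config",
    "default_config",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """Typed view over the raw configuration mapping."""

    raw: dict

    # -- consumption ------------------------------------------------------
    def baseline_profile(self) -> ConsumptionProfile:
        """Deterministic (expected-count) baseline consumption profile."""
        pop = float(self.raw["population"]["nsw_aged_14_plus"])
        block = self.raw["consumption"]
        prevalence = float(block["baseline_prevalence"])
        users = prevalence * pop
        counts = {UseCategory.NONE: pop - users}
        for label, share in block["category_shares"].items():
            counts[UseCategory.from_label(label)] = share * users
        return ConsumptionProfile(
            counts=counts,
            grams_per_use_day={
                UseCategory.from_label(k): float(v)
                for k, v in block["grams_per_use_day"].items()
            },
            use_days_per_year={
                UseCategory.from_label(k): float(v)
                for k, v in block["use_days_per_year"].items()
            },
        )

    def intents(self) -> IntentDistribution:
        block = self.raw["consumption"]["intents"]
        return IntentDistribution(users=dict(block["users"]), non_users=dict(block["non_users"]))

    @property
    def shift_decreasers(self) -> bool:
        return bool(self.raw["consumption"].get("shift_decreasers", False))

    # -- wellbeing --------------------------------------------------------
    @property
    def price_per_gram(self) -> float:
        return float(self.raw["wellbeing"]["price_per_gram"])

    def excluded_share(self, policy: str) -> float:
        return float(self.raw["wellbeing"]["excluded_share"][policy])

    # -- harms ------------------------------------------------------------
    def harm_parameters(self) -> HarmParameters:
        h = self.raw["harms"]
        education = h["education"]
        incarceration = h["incarceration"]
        return HarmParameters(
            nnp={k: dict(v) for k, v in h["nnp"].items()},
            cost_per_case=dict(h["cost_per_case"]),
            cud_rate=float(h["cud"]["rate"]),
            cud_rate_se=float(h["cud"]["rate_se"]),
            cud_first_year_factor=float(h["cud"]["first_year_factor"]),
            treatment_cost_per_case=dict(h["cud"]["treatment_cost_per_case"]),
            p_fatality_per_use_day=float(h["accidents"]["p_fatality_per_use_day"]),
            p_injury_per_use_day=dict(h["accidents"]["p_injury_per_use_day"]),
            injury_cost=dict(h["accidents"]["injury_cost"]),
            vosly=float(h["accidents"]["vosly"]),
            life_years_lost_per_fatality=float(h["accidents"]["life_years_lost_per_fatality"]),
            years_lost_per_affected=float(education["years_lost_per_affected"]),
            earnings_share_per_school_year=float(education["earnings_share_per_school_year"]),
            earnings_share_range=tuple(education["earnings_share_range"]),
            average_earnings=float(education["average_earnings"]),
            minimum_wage_2007=float(incarceration["minimum_wage_2007"]),
            stigma_wtp=float(h["stigma"]["wtp_per_person"]),
            n_new_convictions=float(h["stigma"]["n_new_convictions"]),
            incarcerated_by_offence=dict(incarceration["persons_by_offence"]),
            mean_sentence_years=dict(incarceration["mean_sentence_years"]),
            affected_education=dict(education["affected_persons"]),
        )

    @property
    def status_quo_mental_health_cost(self) -> float:
        return float(self.raw["harms"]["status_quo_schizophrenia_psychosis_cost"])

    # -- market -----------------------------------------------------------
    def market_parameters(self) -> MarketParameters:
        m = self.raw["market"]
        return MarketParameters(
            licence_fee=float(m["licence_fee"]),
            n_licensed=float(m["n_licensed"]),
            n_shops=int(m["n_shops"]),
            staff_per_shop=int(m["staff_per_shop"]),
            hours_per_day=float(m["hours_per_day"]),
            trading_days_per_year=float(m["trading_days_per_year"]),
            composite_hourly_rate=float(m["composite_hourly_rate"]),
            total_grams_sold=float(m["total_grams_sold"]),
            retail_price_per_gram=float(m["retail_price_per_gram"]),
            grower_price_per_gram=float(m["grower_price_per_gram"]),
            grower_price_range=tuple(m["grower_price_range"]),
            farmgate_markup_range=tuple(m["farmgate_markup_range"]),
            leakage=float(m["leakage"]),
            leakage_range=tuple(m["leakage_range"]),
            leakage_on_grower=bool(m["leakage_on_grower"]),
            greenhouse_yield_grams=float(m["greenhouse_yield_grams"]),
            regulator_base_budget_millions=float(m["regulator_base_budget"]),
            regulator_scale=float(m["regulator_scale"]),
            info_quit_per_capita=float(m["info_quit_per_capita"]),
            enforcement_per_capita=float(m["enforcement_per_capita"]),
            population=float(self.raw["population"]["nsw_total"]),
            cannabis_prevalence=float(m["cannabis_prevalence"]),
            tobacco_prevalence=float(m["tobacco_prevalence"]),
            merit_carryover=float(m["merit_carryover"]),
            status_quo_merit_millions=float(m["status_quo_merit"]),
            drug_driving_policing_millions=float(m["drug_driving_policing"]),
        )

    # -- Monte Carlo ------------------------------------------------------
    def monte_carlo(self, **overrides) -> MonteCarloConfig:
        mc = dict(self.raw["monte_carlo"])
        mc["percentiles"] = tuple(mc.get("percentiles", (5, 95)))
        mc.update(overrides)
        return MonteCarloConfig(
            repetitions=int(mc["repetitions"]),
            percentiles=tuple(float(p) for p in mc["percentiles"]),
            seed=int(mc["seed"]),
            sd_rule=str(mc["sd_rule"]),
            truncate_at_zero=bool(mc["truncate_at_zero"]),
        )

    @property
    def synthetic(self) -> dict:
        return dict(self.raw.get("synthetic", {}))


def load_config(path: Union[str, Path, None] = None) -> AnalysisConfig:
    """Load a configuration file; with no path, the packaged default."""
    if path is None:
        source = resources.files("cannabis_cba.data").joinpath("default_config.yaml")
        with resources.as_file(source) as default_path:
            text = Path(default_path).read_text(encoding="utf-8")
    else:
        text = Path(path).read_text(encoding="utf-8")
    raw = yaml.safe_load(text)
    return AnalysisConfig(raw=raw)


def default_config() -> AnalysisConfig:
    return load_config(None)
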