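"""Downstream harm calculators.

Each converts an exposure count (additional users, use days, affected
persons) into expected cases and a monetary component via externally
sourced coefficients held in :class:`HarmParameters`:

* psychosis / schizophrenia incidence via number-needed-to-prevent (NNP)
  denominators, by heavy/light use stratum;
* cannabis-use-disorder (CUD) treatment costs, linear in the number of
  users past the >5-occasions-per-year threshold;
* motor-vehicle accident burden (fatalities valued at the statistical value
  of a life year, injuries at health-system costs), linear in use days;
* income loss from curtailed schooling (years lost x the earnings return
  per school year x average earnings);
* wages forgone while incarcerated, valued at the minimum wage;
* the stigma of acquiring a criminal record, valued at the community's
  willingness to pay to avoid one (status quo only).

All calculators are linear in their exposure argument and keep fractional
expected case counts internally; rounding to whole cases is a reporting
decision, not a modelling one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from .consumption import ConsumptionProfile, USER_CATEGORIES, UseCategory

__all__ = [
    "HarmParameters",
    "CaseBurden",
    "AccidentBurden",
    "attributable_cases",
    "attributable_case_burden",
    "cud_treatment_cost",
    "accident_burden",
    "education_loss",
    "incarceration_wage_loss",
    "stigma_value",
    "delta_users_by_stratum",
    "cud_eligible_users",
]

#: Categories counted as "heavy" use for the NNP strata.
HEAVY_CATEGORIES = (UseCategory.AT_LEAST_WEEKLY, UseCategory.DAILY)


@dataclass(frozen=True)
class HarmParameters:
    """Externally sourced coefficients feeding the harm calculators.

    Probabilities are per use day; monetary coefficients are in AUD per
    case, per person or per life-year (component outputs are reported in
    millions).  ``nnp`` maps condition -> stratum -> users-prevented per
    case; ``treatment_cost_per_case`` and ``affected_education`` map policy
    name -> value, because the published rows they reproduce differ by
    policy.
    """

    nnp: Mapping[str, Mapping[str, float]]
    cost_per_case: Mapping[str, float]
    cud_rate: float
    cud_rate_se: float
    cud_first_year_factor: float
    treatment_cost_per_case: Mapping[str, float]
    p_fatality_per_use_day: float
    p_injury_per_use_day: Mapping[str, float]
    injury_cost: Mapping[str, float]
    vosly: float
    life_years_lost_per_fatality: float
    years_lost_per_affected: float
    earnings_share_per_school_year: float
    earnings_share_range: tuple[float, float]
    average_earnings: float
    minimum_wage_2007: float
    stigma_wtp: float
    n_new_convictions: float
    incarcerated_by_offence: Mapping[str, float]
    mean_sentence_years: Mapping[str, float]
    affected_education: Mapping[str, float]

    def __post_init__(self) -> None:
        for condition, strata in self.nnp.items():
            for stratum, value in strata.items():
                if value <= 0:
                    raise ValueError(f"NNP for {condition}/{stratum} must be positive")
        probs = {"p_fatality_per_use_day": self.p_fatality_per_use_day}
        probs.update({f"p_injury[{k}]": v for k, v in self.p_injury_per_use_day.items()})
        probs["cud_rate"] = self.cud_rate
        probs["cud_first_year_factor"] = self.cud_first_year_factor
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} is not a probability")
        if not 0.0 < self.earnings_share_per_school_year < 1.0:
            raise ValueError("earnings_share_per_school_year must lie in (0, 1)")

    @property
    def value_per_fatality(self) -> float:
        return self.vosly * self.life_years_lost_per_fatality


@dataclass(frozen=True)
class CaseBurden:
    """Expected cases and their cost for one condition."""

    cases: float
    cost_millions: float


@dataclass(frozen=True)
class AccidentBurden:
    """Expected road-accident outcomes and their monetary components.

    ``mortality_value_millions`` is the life-year valuation of fatalities
    (a lost benefit); ``injury_cost_millions`` the health-system cost of
    treating injuries (a cost).  The two are kept apart because they land
    in different ledger blocks.
    """

    fatalities: float
    injuries: Mapping[str, float]
    mortality_value_millions: float
    injury_cost_millions: float

    @property
    def total_cost_millions(self) -> float:
        return self.mortality_value_millions + self.injury_cost_millions


def attributable_cases(
    additional_users: Mapping[str, float], nnp: Mapping[str, float]
) -> float:
    """Expected new cases: sum over strata of additional users / NNP."""
    cases = 0.0
    for stratum, users in additional_users.items():
        if users < 0:
            raise ValueError(f"additional users for {stratum!r} is negative")
        denominator = nnp.get(stratum)
        if denominator is None:
            raise ValueError(f"no NNP supplied for stratum {stratum!r}")
        if denominator <= 0:
            raise ValueError(f"NNP for {stratum!r} must be positive")
        cases += users / denominator
    return cases


def attributable_case_burden(
    additional_users: Mapping[str, float], params: HarmParameters
) -> dict[str, CaseBurden]:
    """Cases and costs per condition for a given change in user numbers."""
    out = {}
    for condition, nnp in params.nnp.items():
        cases = attributable_cases(additional_users, nnp)
        out[condition] = CaseBurden(
            cases=cases,
            cost_millions=cases * params.cost_per_case[condition] / 1e6,
        )
    return out


def cud_treatment_cost(
    eligible_users: float, cud_rate: float, treatment_cost_per_case: float
) -> float:
    """Annual CUD treatment cost in millions AUD, linear in eligible users
    (those consuming on more than five occasions a year)."""
    if eligible_users < 0 or cud_rate < 0 or treatment_cost_per_case < 0:
        raise ValueError("cud_treatment_cost arguments must be non-negative")
    return eligible_users * cud_rate * treatment_cost_per_case / 1e6


def accident_burden(use_days: float, params: HarmParameters) -> AccidentBurden:
    """Expected accident outcomes for a number of use days.

    Pass total use days for a level estimate, or a difference in use days
    between policies for an incremental one; the calculator is linear so
    the two views are consistent.
    """
    if use_days < 0:
        raise ValueError("use_days must be non-negative")
    fatalities = params.p_fatality_per_use_day * use_days
    injuries = {
        severity: p * use_days for severity, p in params.p_injury_per_use_day.items()
    }
    injury_cost = sum(
        injuries[severity] * params.injury_cost[severity] for severity in injuries
    )
    return AccidentBurden(
        fatalities=fatalities,
        injuries=injuries,
        mortality_value_millions=fatalities * params.value_per_fatality / 1e6,
        injury_cost_millions=injury_cost / 1e6,
    )


def education_loss(
    affected_persons: float,
    years_lost_per_affected: float,
    average_earnings: float,
    earnings_share_per_school_year: float,
) -> float:
    """Annual income forgone from curtailed schooling, in millions AUD.

    Years of schooling lost are valued at the earnings return per school
    year (default 10%, range 8-12%) applied to average earnings.
    """
    for name, value in (
        ("affected_persons", affected_persons),
        ("years_lost_per_affected", years_lost_per_affected),
        ("average_earnings", average_earnings),
        ("earnings_share_per_school_year", earnings_share_per_school_year),
    ):
        if value < 0:
            raise ValueError(f"{name} must be non-negative")
    return (
        affected_persons
        * years_lost_per_affected
        * earnings_share_per_school_year
        * average_earnings
        / 1e6
    )


def incarceration_wage_loss(
    n_by_offence: Mapping[str, float],
    mean_sentence_years: Mapping[str, float],
    minimum_wage_annual: float,
) -> float:
    """Wages forgone while incarcerated, in millions AUD: persons x average
    sentence x the annual minimum wage, summed over offence types.
    Applies to the status quo only (no imprisonment for use under
    legalisation)."""
    if minimum_wage_annual < 0:
        raise ValueError("minimum_wage_annual must be non-negative")
    total = 0.0
    for offence, n in n_by_offence.items():
        if n < 0:
            raise ValueError(f"incarcerated count for {offence!r} is negative")
        duration = mean_sentence_years.get(offence)
        if duration is None:
            raise ValueError(f"no mean sentence supplied for offence {offence!r}")
        if duration < 0:
            raise ValueError(f"mean sentence for {offence!r} is negative")
        total += n * duration * minimum_wage_annual
    return total / 1e6


def stigma_value(n_new_convictions: float, stigma_wtp: float) -> float:
    """Value of the stigma from newly acquired criminal records, in millions
    AUD.  Zero under legalisation, where no such convictions occur."""
    if n_new_convictions < 0 or stigma_wtp < 0:
        raise ValueError("stigma_value arguments must be non-negative")
    return n_new_convictions * stigma_wtp / 1e6


def delta_users_by_stratum(
    baseline: ConsumptionProfile, shifted: ConsumptionProfile
) -> dict[str, float]:
    """Additional users by heavy/light stratum between two profiles.

    Heavy use is at-least-weekly or daily.  Negative deltas are floored at
    zero: the NNP calculators model additional incident cases, not
    remission.
    """

    def count(profile: ConsumptionProfile, cats) -> float:
        return sum(profile.counts.get(cat, 0.0) for cat in cats)

    light_cats = tuple(c for c in USER_CATEGORIES if c not in HEAVY_CATEGORIES)
    return {
        "heavy": max(0.0, count(shifted, HEAVY_CATEGORIES) - count(baseline, HEAVY_CATEGORIES)),
        "light": max(0.0, count(shifted, light_cats) - count(baseline, light_cats)),
    }


def cud_eligible_users(
    baseline: ConsumptionProfile,
    shifted: ConsumptionProfile,
    first_year_factor: float = 1.0,
) -> tuple[float, float]:
    """Users past the >5-occasion threshold under each policy.

    Every baseline use category qualifies (the lightest averages six use
    days a year).  New users recruited by legalisation reach the threshold
    in their first year only at ``first_year_factor``; continuing users
    always count.
    """
    if not 0.0 <= first_year_factor <= 1.0:
        raise ValueError("first_year_factor must lie in [0, 1]")
    eligible_sq = baseline.n_users
    new_users = max(0.0, shifted.n_users - baseline.n_users)
    eligible_lr = eligible_sq + first_year_factor * new_users
    return eligible_sq, eligible_lr
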