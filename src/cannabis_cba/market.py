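"""The legalised-regulated supply side.

Distribution and retail run through a government (or other non-profit)
monopoly: 330 cannabis-only shops, two staff, twelve trading hours a day,
selling at the unchanged street price.  Consumers hold a $45/year licence;
contracted growers are paid a farm-gate price two to three-and-a-half-fold
below retail.  A black market plus home growing leaks 15% (10-20%) of
potential revenue.  Public costs cover the regulator (benchmarked on the
poppy control board), enforcement and consumer-information programs
(tobacco-control per-capita benchmarks rescaled by relative prevalence),
and the retained share of the court-diversion program.

Revenue is a transfer payment, so none of this enters the default net
social benefit; the revenue statement feeds the with-revenue variant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

__all__ = [
    "MarketParameters",
    "RevenueStatement",
    "licence_cost",
    "retail_operating_cost",
    "revenue_statement",
    "legalised_public_costs",
    "grower_greenhouse_receipts",
]


@dataclass(frozen=True)
class MarketParameters:
    """Supply-side parameters; monetary fields in AUD unless suffixed
    ``_millions``."""

    licence_fee: float = 45.0
    n_licensed: float = 691_111.0
    n_shops: int = 330
    staff_per_shop: int = 2
    hours_per_day: float = 12.0
    trading_days_per_year: float = 365.0
    composite_hourly_rate: float = 28.663345786633457
    total_grams_sold: float = 80_000_000.0
    retail_price_per_gram: float = 20.0
    grower_price_per_gram: float = 7.71875
    grower_price_range: tuple[float, float] = (5.5, 8.8)
    farmgate_markup_range: tuple[float, float] = (2.0, 3.5)
    leakage: float = 0.15
    leakage_range: tuple[float, float] = (0.10, 0.20)
    leakage_on_grower: bool = False
    greenhouse_yield_grams: float = 7_200_000.0
    regulator_base_budget_millions: float = 2.0 / 3.0
    regulator_scale: float = 1.5
    info_quit_per_capita: float = 2.838381946720352
    enforcement_per_capita: float = 0.9082822229505126
    population: float = 6_890_000.0
    cannabis_prevalence: float = 0.124
    tobacco_prevalence: float = 0.194
    merit_carryover: float = 0.65
    status_quo_merit_millions: float = 3.5
    drug_driving_policing_millions: float = 11.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.leakage <= 1.0:
            raise ValueError("leakage must lie in [0, 1]")
        if not 0.0 <= self.merit_carryover <= 1.0:
            raise ValueError("merit_carryover must lie in [0, 1]")
        if self.retail_price_per_gram <= 0 or self.grower_price_per_gram <= 0:
            raise ValueError("prices must be positive")


@dataclass(frozen=True)
class RevenueStatement:
    """Annual retail-monopoly accounts, millions of 2007 AUD."""

    gross_millions: float          # collected sales revenue, net of leakage
    grower_payments_millions: float
    operating_cost_millions: float
    leaked_millions: float         # potential revenue lost to the black market
    net_millions: float            # gross - grower payments - operating cost


def licence_cost(n_licensed: float, licence_fee: float) -> float:
    """Total personal licensing cost, millions AUD (a cost to consumers)."""
    if n_licensed < 0 or licence_fee < 0:
        raise ValueError("licence_cost arguments must be non-negative")
    return n_licensed * licence_fee / 1e6


def retail_operating_cost(
    params: MarketParameters, fixed_overheads_millions: float = 0.0
) -> float:
    """Annual cost of running the shop network, millions AUD.

    shops x staff x hours x trading days, at a composite hourly rate that
    folds wages and per-hour overheads together (the split is not published;
    the default rate is back-solved in the packaged config).
    """
    if min(params.n_shops, params.staff_per_shop, params.hours_per_day) < 0:
        raise ValueError("staffing inputs must be non-negative")
    staffed_hours = (
        params.n_shops
        * params.staff_per_shop
        * params.hours_per_day
        * params.trading_days_per_year
    )
    return staffed_hours * params.composite_hourly_rate / 1e6 + fixed_overheads_millions


def revenue_statement(
    total_grams_sold: float,
    retail_price: float,
    grower_price: float,
    operating_cost_millions: float,
    leakage: float,
    leakage_on_grower: bool = False,
) -> RevenueStatement:
    """Gross and net government revenue from monopoly retail.

    Leakage removes a share of potential sales revenue.  By default growers
    are paid for their full contracted supply (the leaked share is served
    by the black market and home growing, not by shorting the contracts);
    ``leakage_on_grower=True`` scales grower payments down by the same
    leakage factor instead.
    """
    if grower_price >= retail_price:
        raise ValueError(
            f"grower price {grower_price} must be below retail price {retail_price}"
        )
    if not 0.0 <= leakage <= 1.0:
        raise ValueError("leakage must lie in [0, 1]")
    if total_grams_sold < 0:
        raise ValueError("total_grams_sold must be non-negative")
    potential = total_grams_sold * retail_price / 1e6
    gross = potential * (1.0 - leakage)
    leaked = potential * leakage
    grower_factor = (1.0 - leakage) if leakage_on_grower else 1.0
    grower_payments = total_grams_sold * grower_price * grower_factor / 1e6
    net = gross - grower_payments - operating_cost_millions
    return RevenueStatement(
        gross_millions=gross,
        grower_payments_millions=grower_payments,
        operating_cost_millions=operating_cost_millions,
        leaked_millions=leaked,
        net_millions=net,
    )


def legalised_public_costs(params: MarketParameters) -> dict[str, float]:
    """Public cost components of the legalised-regulated model, millions AUD.

    * ``regulator``: poppy-control-board benchmark scaled up 50% for the
      larger area and year-round cultivation;
    * ``enforcement`` and ``info_quit``: tobacco-control per-capita
      benchmarks x population, rescaled by cannabis vs tobacco prevalence;
    * ``merit``: the retained 65% of status-quo court-diversion spending
      (0.65 x 3.5 = 2.275; the published row rounds this to 2.5);
    * ``drug_driving_policing``: roadside drug-testing police costs.
    """
    prevalence_ratio = params.cannabis_prevalence / params.tobacco_prevalence
    return {
        "regulator": params.regulator_base_budget_millions * params.regulator_scale,
        "enforcement": params.enforcement_per_capita
        * params.population
        * prevalence_ratio
        / 1e6,
        "info_quit": params.info_quit_per_capita
        * params.population
        * prevalence_ratio
        / 1e6,
        "merit": params.merit_carryover * params.status_quo_merit_millions,
        "drug_driving_policing": params.drug_driving_policing_millions,
    }


def grower_greenhouse_receipts(
    grower_price: float, greenhouse_yield_grams: float
) -> float:
    """Annual receipts of one one-acre greenhouse at a farm-gate price,
    millions AUD."""
    if grower_price < 0 or greenhouse_yield_grams < 0:
        raise ValueError("grower_greenhouse_receipts arguments must be non-negative")
    return grower_price * greenhouse_yield_grams / 1e6
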