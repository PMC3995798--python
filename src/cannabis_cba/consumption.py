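"""Prevalence and consumption shift model, and the wellbeing proxy.

The legalisation scenario is driven by a single survey question put to
household-survey respondents: *"if cannabis were legal to use, would you
(not use, decrease, try it, increase, or not change use)?"*.  Current users
who answer "increase" are shifted up one use-frequency category (monthly
becomes at-least-weekly, at-least-weekly becomes daily; daily saturates);
non-users who answer "try it" are distributed across the existing user
categories in proportion to the baseline use pattern.  Price is held
constant, so the whole change in demand is attributed to legal status.

Wellbeing from consumption has no direct monetary metric; the proxy valued
here is eligible quantity consumed times the median street price, where
grams consumed by people under 21 or with a cannabis use disorder are
excluded from "eligible".
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

__all__ = [
    "UseCategory",
    "USER_CATEGORIES",
    "ConsumptionProfile",
    "IntentDistribution",
    "shift_profile",
    "prevalence_change",
    "wellbeing_value",
    "elasticity_scenario",
]

_SUM_TOL = 1e-9


class UseCategory(enum.IntEnum):
    """Ordered use-frequency categories; ``NONE`` means no past-year use."""

    NONE = 0
    LESS_THAN_MONTHLY = 1
    MONTHLY = 2
    AT_LEAST_WEEKLY = 3
    DAILY = 4

    @property
    def label(self) -> str:
        return self.name.lower()

    @classmethod
    def from_label(cls, label: str) -> "UseCategory":
        return cls[label.upper()]

    def shifted_up(self) -> "UseCategory":
        """One category heavier; daily use saturates at daily."""
        return UseCategory(min(self.value + 1, UseCategory.DAILY.value))

    def shifted_down(self) -> "UseCategory":
        return UseCategory(max(self.value - 1, UseCategory.NONE.value))


USER_CATEGORIES: tuple[UseCategory, ...] = (
    UseCategory.LESS_THAN_MONTHLY,
    UseCategory.MONTHLY,
    UseCategory.AT_LEAST_WEEKLY,
    UseCategory.DAILY,
)


@dataclass(frozen=True)
class ConsumptionProfile:
    """Population counts by use category plus per-category intensity.

    Counts may be fractional: the shift model works in expectation by
    default, matching the deterministic aggregates it reproduces.  Intensity
    (grams per use day, use days per year) attaches to the category, so a
    person moving category adopts the destination intensity.
    """

    counts: Mapping[UseCategory, float]
    grams_per_use_day: Mapping[UseCategory, float]
    use_days_per_year: Mapping[UseCategory, float]

    def __post_init__(self) -> None:
        counts = {UseCategory(k): float(v) for k, v in self.counts.items()}
        counts.setdefault(UseCategory.NONE, 0.0)
        for cat, n in counts.items():
            if n < 0:
                raise ValueError(f"negative count for {cat.label}: {n}")
        for cat in counts:
            if cat is UseCategory.NONE:
                continue
            if cat not in self.grams_per_use_day or cat not in self.use_days_per_year:
                raise ValueError(f"missing intensity for category {cat.label}")
        object.__setattr__(self, "counts", counts)

    @property
    def population(self) -> float:
        return float(sum(self.counts.values()))

    @property
    def n_users(self) -> float:
        return self.population - self.counts.get(UseCategory.NONE, 0.0)

    @property
    def prevalence(self) -> float:
        pop = self.population
        if pop == 0:
            raise ValueError("prevalence undefined for zero population")
        return self.n_users / pop

    @property
    def total_grams(self) -> float:
        return float(
            sum(
                self.counts.get(cat, 0.0)
                * self.use_days_per_year[cat]
                * self.grams_per_use_day[cat]
                for cat in USER_CATEGORIES
                if cat in self.counts
            )
        )

    @property
    def total_use_days(self) -> float:
        return float(
            sum(
                self.counts.get(cat, 0.0) * self.use_days_per_year[cat]
                for cat in USER_CATEGORIES
                if cat in self.counts
            )
        )

    def user_shares(self) -> dict[UseCategory, float]:
        """Baseline distribution of users across categories (sums to 1)."""
        users = self.n_users
        if users <= 0:
            raise ValueError("no current users: user shares undefined")
        return {
            cat: self.counts.get(cat, 0.0) / users
            for cat in USER_CATEGORIES
            if cat in self.counts
        }


@dataclass(frozen=True)
class IntentDistribution:
    """Responses to the intent-under-legalisation question.

    ``users`` holds proportions over {not_use, decrease, increase,
    no_change} among current users, ``non_users`` over {try_it, not_use}
    among non-users.  Each set must be non-negative and sum to one.
    """

    users: Mapping[str, float] = field(
        default_factory=lambda: {"not_use": 0.0, "decrease": 0.0, "increase": 0.0, "no_change": 1.0}
    )
    non_users: Mapping[str, float] = field(
        default_factory=lambda: {"try_it": 0.0, "not_use": 1.0}
    )

    def __post_init__(self) -> None:
        self._check(self.users, ("not_use", "decrease", "increase", "no_change"), "users")
        self._check(self.non_users, ("try_it", "not_use"), "non_users")

    @staticmethod
    def _check(props: Mapping[str, float], keys: tuple[str, ...], which: str) -> None:
        unknown = set(props) - set(keys)
        if unknown:
            raise ValueError(f"unknown {which} intent(s): {sorted(unknown)}")
        for key in keys:
            if props.get(key, 0.0) < 0:
                raise ValueError(f"{which} intent {key!r} is negative")
        total = sum(props.get(key, 0.0) for key in keys)
        if abs(total - 1.0) > _SUM_TOL:
            raise ValueError(f"{which} intent proportions sum to {total}, not 1")


class PrevalenceShift(NamedTuple):
    relative_prevalence_change: float
    new_population_rate: float
    relative_consumption_change: float


def shift_profile(
    baseline: ConsumptionProfile,
    intents: IntentDistribution,
    shift_decreasers: bool = False,
) -> ConsumptionProfile:
    """Apply the intent-to-change responses to a baseline profile.

    Population is conserved exactly.  "Increase" respondents move up one
    category; "try it" non-users are allocated across user categories
    proportionally to the baseline user shares.  "Decrease" and current-user
    "not use" respondents are left unchanged by default (the published model
    states no rule for them); with ``shift_decreasers=True`` decreasers move
    down one category and "not use" respondents stop using.
    """
    counts = {cat: baseline.counts.get(cat, 0.0) for cat in UseCategory}
    new = dict(counts)

    p_inc = intents.users.get("increase", 0.0)
    p_dec = intents.users.get("decrease", 0.0)
    p_not = intents.users.get("not_use", 0.0)
    for cat in USER_CATEGORIES:
        n = counts[cat]
        if n == 0:
            continue
        movers_up = p_inc * n
        new[cat] -= movers_up
        new[cat.shifted_up()] += movers_up
        if shift_decreasers:
            new[cat] -= p_dec * n
            new[cat.shifted_down()] += p_dec * n
            new[cat] -= p_not * n
            new[UseCategory.NONE] += p_not * n

    triers = intents.non_users.get("try_it", 0.0) * counts[UseCategory.NONE]
    if triers > 0:
        shares = baseline.user_shares()  # raises if there is no use pattern to copy
        new[UseCategory.NONE] -= triers
        for cat, share in shares.items():
            new[cat] += triers * share

    return ConsumptionProfile(
        counts=new,
        grams_per_use_day=baseline.grams_per_use_day,
        use_days_per_year=baseline.use_days_per_year,
    )


def prevalence_change(
    baseline: ConsumptionProfile, shifted: ConsumptionProfile
) -> PrevalenceShift:
    """Relative prevalence change, new population rate, and relative change
    in total grams consumed, between a baseline and a shifted profile."""
    pop = baseline.population
    if pop == 0:
        raise ValueError("rates undefined for zero population")
    if abs(shifted.population - pop) > 1e-6 * max(pop, 1.0):
        raise ValueError("profiles do not share a population")
    base_rate = baseline.prevalence
    new_rate = shifted.prevalence
    if base_rate == 0:
        raise ValueError("relative prevalence change undefined: no baseline users")
    base_grams = baseline.total_grams
    if base_grams == 0:
        raise ValueError("relative consumption change undefined: zero baseline grams")
    return PrevalenceShift(
        relative_prevalence_change=new_rate / base_rate - 1.0,
        new_population_rate=new_rate,
        relative_consumption_change=shifted.total_grams / base_grams - 1.0,
    )


def wellbeing_value(
    profile: ConsumptionProfile, price_per_gram: float, excluded_grams: float = 0.0
) -> float:
    """Wellbeing proxy: eligible grams times street price, in millions AUD.

    ``excluded_grams`` removes consumption by people under 21 or with a
    cannabis use disorder, whose consumption is not counted as wellbeing.
    """
    if price_per_gram <= 0:
        raise ValueError("price_per_gram must be positive")
    total = profile.total_grams
    if excluded_grams < 0 or excluded_grams > total:
        raise ValueError(
            f"excluded_grams={excluded_grams} outside [0, total_grams={total}]"
        )
    return (total - excluded_grams) * price_per_gram / 1e6


def elasticity_scenario(
    base_wellbeing: float, price_change: float, elasticity: float
) -> float:
    """Wellbeing under a price-change thought experiment, in millions AUD.

    Quantity responds to the price change with the given (absolute)
    elasticity — a decrease of ``|price_change|`` scales quantity by
    ``1 + elasticity * |price_change|``, an increase by
    ``1 - elasticity * |price_change|`` — but the new quantity is valued at
    the *original* price, keeping the valuation comparable with the
    constant-price base case.
    """
    if elasticity < 0:
        raise ValueError("elasticity must be non-negative")
    if price_change < 0:
        factor = 1.0 + elasticity * abs(price_change)
    elif price_change > 0:
        factor = 1.0 - elasticity * abs(price_change)
    else:
        factor = 1.0
    if factor < 0:
        raise ValueError(
            f"price change {price_change} at elasticity {elasticity} "
            "implies negative quantity"
        )
    return base_wellbeing * factor
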