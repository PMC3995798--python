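"""Synthetic individual-level survey records.

Generates household-survey-like microdata (one row per person: age,
use-frequency category, grams per use day, use days per year, cannabis-use
disorder, intent-under-legalisation response, prior criminal record) with
the statistical structure the aggregate analysis assumes, so the
consumption and harm stages can be exercised end to end without any
external data.  The generator emulates the *inputs* the analysis consumed;
it is a sampling model calibrated to the same aggregates, not a re-release
of any survey.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import AnalysisConfig, default_config
from .consumption import (
    ConsumptionProfile,
    IntentDistribution,
    USER_CATEGORIES,
    UseCategory,
)

__all__ = [
    "GeneratorConfig",
    "generate_population",
    "aggregate_profile",
    "estimate_intents",
]

_USER_INTENTS = ("not_use", "decrease", "increase", "no_change")
_NONUSER_INTENTS = ("try_it", "not_use")


@dataclass(frozen=True)
class GeneratorConfig:
    """Sampling configuration for one synthetic population."""

    n: int
    baseline_prevalence: float = 0.086
    category_shares: Mapping[UseCategory, float] = field(
        default_factory=lambda: {
            UseCategory.LESS_THAN_MONTHLY: 0.46,
            UseCategory.MONTHLY: 0.17,
            UseCategory.AT_LEAST_WEEKLY: 0.22,
            UseCategory.DAILY: 0.15,
        }
    )
    intents: IntentDistribution = field(default_factory=IntentDistribution)
    grams_per_use_day: Mapping[UseCategory, float] = field(
        default_factory=lambda: {
            UseCategory.LESS_THAN_MONTHLY: 0.3,
            UseCategory.MONTHLY: 0.4,
            UseCategory.AT_LEAST_WEEKLY: 0.6,
            UseCategory.DAILY: 1.0,
        }
    )
    use_days_per_year: Mapping[UseCategory, float] = field(
        default_factory=lambda: {
            UseCategory.LESS_THAN_MONTHLY: 6.0,
            UseCategory.MONTHLY: 18.0,
            UseCategory.AT_LEAST_WEEKLY: 110.0,
            UseCategory.DAILY: 365.0,
        }
    )
    grams_noise_sigma: float = 0.35
    cud_rate: float = 0.20
    under21_share: float = 0.12
    prior_record_share: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("n must be non-negative")
        for name, value in (
            ("baseline_prevalence", self.baseline_prevalence),
            ("cud_rate", self.cud_rate),
            ("under21_share", self.under21_share),
            ("prior_record_share", self.prior_record_share),
        ):
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name}={value} is not a fraction in [0, 1]")
        total = sum(self.category_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"category shares sum to {total}, not 1")
        if any(v < 0 for v in self.category_shares.values()):
            raise ValueError("category shares must be non-negative")

    @classmethod
    def from_analysis_config(
        cls, config: Optional[AnalysisConfig] = None, n: Optional[int] = None, seed: Optional[int] = None
    ) -> "GeneratorConfig":
        """Build the generator from the packaged analysis defaults, so the
        synthetic population's expectation matches the deterministic model."""
        config = config or default_config()
        block = config.raw["consumption"]
        synthetic = config.synthetic
        return cls(
            n=int(n if n is not None else synthetic.get("n", 100_000)),
            baseline_prevalence=float(block["baseline_prevalence"]),
            category_shares={
                UseCategory.from_label(k): float(v)
                for k, v in block["category_shares"].items()
            },
            intents=config.intents(),
            grams_per_use_day={
                UseCategory.from_label(k): float(v)
                for k, v in block["grams_per_use_day"].items()
            },
            use_days_per_year={
                UseCategory.from_label(k): float(v)
                for k, v in block["use_days_per_year"].items()
            },
            grams_noise_sigma=float(synthetic.get("grams_noise_sigma", 0.35)),
            cud_rate=float(config.raw["harms"]["cud"]["rate"]),
            under21_share=float(synthetic.get("under21_share", 0.12)),
            prior_record_share=float(synthetic.get("prior_record_share", 0.08)),
            seed=int(seed if seed is not None else synthetic.get("seed", 0)),
        )


def generate_population(config: GeneratorConfig) -> pd.DataFrame:
    """Draw one synthetic population as a data frame of person records.

    Reproducible by seed.  Invariants: non-users have zero use days and
    answer only the non-user intent options; cannabis-use disorder occurs
    only among people using on more than five occasions a year; grams per
    use day are lognormal around the category mean (mean-preserving).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n
    columns = [
        "age",
        "use_category",
        "grams_per_use_day",
        "use_days_per_year",
        "cud",
        "intent",
        "prior_record",
    ]
    if n == 0:
        return pd.DataFrame({c: [] for c in columns})

    is_user = rng.random(n) < config.baseline_prevalence
    cats = np.full(n, UseCategory.NONE.value, dtype=np.int64)
    n_users = int(is_user.sum())
    share_cats = list(config.category_shares)
    share_p = np.array([config.category_shares[c] for c in share_cats])
    share_p = share_p / share_p.sum()
    cats[is_user] = rng.choice([c.value for c in share_cats], size=n_users, p=share_p)

    # age only supports the under-21 wellbeing exclusion: users are a
    # two-point mixture of 14-20 and 21-65, non-users uniform 14-80
    age = rng.uniform(14.0, 80.0, size=n)
    under21 = rng.random(n) < config.under21_share
    age[is_user & under21] = rng.uniform(14.0, 21.0, size=int((is_user & under21).sum()))
    age[is_user & ~under21] = rng.uniform(21.0, 65.0, size=int((is_user & ~under21).sum()))

    grams = np.zeros(n)
    days = np.zeros(n)
    sigma = config.grams_noise_sigma
    for cat in USER_CATEGORIES:
        mask = cats == cat.value
        count = int(mask.sum())
        if count == 0:
            continue
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=count)
        grams[mask] = config.grams_per_use_day[cat] * noise
        days[mask] = config.use_days_per_year[cat]

    cud = np.zeros(n, dtype=bool)
    eligible = days > 5  # disorder requires use on more than five occasions
    cud[eligible] = rng.random(int(eligible.sum())) < config.cud_rate

    intent = np.empty(n, dtype=object)
    user_p = np.array([config.intents.users.get(k, 0.0) for k in _USER_INTENTS])
    nonuser_p = np.array([config.intents.non_users.get(k, 0.0) for k in _NONUSER_INTENTS])
    intent[is_user] = rng.choice(_USER_INTENTS, size=n_users, p=user_p / user_p.sum())
    intent[~is_user] = rng.choice(
        _NONUSER_INTENTS, size=n - n_users, p=nonuser_p / nonuser_p.sum()
    )

    prior_record = rng.random(n) < config.prior_record_share

    return pd.DataFrame(
        {
            "age": age,
            "use_category": [UseCategory(c).label for c in cats],
            "grams_per_use_day": grams,
            "use_days_per_year": days,
            "cud": cud,
            "intent": intent,
            "prior_record": prior_record,
        }
    )


def aggregate_profile(population: pd.DataFrame) -> ConsumptionProfile:
    """Collapse person records into a consumption profile.

    Category counts, the empirical mean grams per use day and the mean use
    days per category.  Order-independent: any permutation of the records
    aggregates identically.
    """
    if len(population) == 0:
        return ConsumptionProfile(
            counts={UseCategory.NONE: 0.0},
            grams_per_use_day={c: 0.0 for c in USER_CATEGORIES},
            use_days_per_year={c: 0.0 for c in USER_CATEGORIES},
        )
    counts: dict[UseCategory, float] = {}
    grams: dict[UseCategory, float] = {}
    days: dict[UseCategory, float] = {}
    labels = population["use_category"]
    for cat in UseCategory:
        mask = labels == cat.label
        counts[cat] = float(mask.sum())
        if cat is UseCategory.NONE:
            continue
        if counts[cat] > 0:
            grams[cat] = float(population.loc[mask, "grams_per_use_day"].mean())
            days[cat] = float(population.loc[mask, "use_days_per_year"].mean())
        else:
            grams[cat] = 0.0
            days[cat] = 0.0
    return ConsumptionProfile(counts=counts, grams_per_use_day=grams, use_days_per_year=days)


def estimate_intents(population: pd.DataFrame) -> IntentDistribution:
    """Empirical intent distribution of a synthetic population."""
    is_user = population["use_category"] != UseCategory.NONE.label
    users = population.loc[is_user, "intent"]
    non_users = population.loc[~is_user, "intent"]

    def proportions(series: pd.Series, keys: tuple[str, ...]) -> dict[str, float]:
        if len(series) == 0:
            fallback = {k: 0.0 for k in keys}
            fallback[keys[-1]] = 1.0
            return fallback
        freq = series.value_counts(normalize=True)
        props = {k: float(freq.get(k, 0.0)) for k in keys}
        return props

    return IntentDistribution(
        users=proportions(users, _USER_INTENTS),
        non_users=proportions(non_users, _NONUSER_INTENTS),
    )
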