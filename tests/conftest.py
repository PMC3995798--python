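from __future__ import annotations

import pytest

from cannabis_cba import (
    ConsumptionProfile,
    UseCategory,
    default_config,
    load_legalised_regulated,
    load_status_quo,
)

GPD = {
    UseCategory.LESS_THAN_MONTHLY: 0.3,
    UseCategory.MONTHLY: 0.4,
    UseCategory.AT_LEAST_WEEKLY: 0.6,
    UseCategory.DAILY: 1.0,
}
DAYS = {
    UseCategory.LESS_THAN_MONTHLY: 6.0,
    UseCategory.MONTHLY: 18.0,
    UseCategory.AT_LEAST_WEEKLY: 110.0,
    UseCategory.DAILY: 365.0,
}


def make_profile(counts, grams_per_use_day=None, use_days=None) -> ConsumptionProfile:
    """Small-profile builder for tests; default NDSHS-like intensities."""
    return ConsumptionProfile(
        counts=counts,
        grams_per_use_day=grams_per_use_day or GPD,
        use_days_per_year=use_days or DAYS,
    )


@pytest.fixture(scope="session")
def sq_ledger():
    return load_status_quo()


@pytest.fixture(scope="session")
def lr_ledger():
    return load_legalised_regulated()


@pytest.fixture(scope="session")
def config():
    return default_config()
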