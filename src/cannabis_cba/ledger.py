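"""Component ledger for a two-policy cost-benefit analysis.

Every cost or benefit enters the analysis as a named *component* carrying a
main estimate and a (low, high) uncertainty range, all in millions of 2007
Australian dollars.  Magnitudes are stored positive; the ``flow`` field
carries the direction:

``cost``
    expenditure by government or individuals (criminal justice, health care,
    licensing, ...); subtracts from the net social benefit (NSB).
``benefit``
    a valued gain to individuals (the wellbeing proxy); adds to the NSB.
``disbenefit``
    a lost benefit (forgone earnings from curtailed schooling, stigma of a
    criminal record, lost wages while incarcerated, statistical life-years
    lost in crashes); subtracts from the NSB.
``revenue`` / ``revenue_expense``
    the retail-monopoly block (gross sales, payments to growers, shop
    operating costs).  Revenue is a transfer payment, so these rows are
    excluded from the default NSB (``include_in_nsb`` is false) and enter
    only when the with-revenue variant is requested.

Subtotal rows of the source table are never stored; block totals are always
recomputed with :func:`sum_flows`, which is what makes the published totals
usable as independent checks rather than inputs.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Union

import math

import pandas as pd

__all__ = [
    "Policy",
    "Category",
    "Flow",
    "ComponentEstimate",
    "Ledger",
    "LedgerSchemaError",
    "LedgerValidationError",
    "read_ledger",
    "write_ledger",
    "sum_flows",
    "apply_default_range",
    "load_status_quo",
    "load_legalised_regulated",
]

#: Absolute slack allowed between a printed main estimate and its printed
#: range before validation rejects the row.  The source table is rounded to
#: one or two decimals ("due to rounding not all totals may not sum
#: exactly"), and one row (parents' lost work time) prints a main of 0.1
#: against a range of (0.04, 0.07).
ROUNDING_SLACK = 0.05

CURRENCY_YEAR = 2007
UNITS = "millions AUD"


class LedgerSchemaError(ValueError):
    """A ledger file is missing a required column or has an unreadable one."""


class LedgerValidationError(ValueError):
    """A ledger row violates a component invariant (named in the message)."""


class Policy(str, enum.Enum):
    STATUS_QUO = "status_quo"
    LEGALISED_REGULATED = "legalised_regulated"
    BOTH = "both"


class Category(str, enum.Enum):
    """The five-way classification of costs and benefits."""

    DIRECT_INTERVENTION = "direct_intervention"
    OTHER_AGENCIES = "other_agencies"
    INDIVIDUAL_BENEFITS = "individual_benefits"
    EXTERNALITIES = "externalities"
    SPILLOVER = "spillover"


class Flow(str, enum.Enum):
    COST = "cost"
    BENEFIT = "benefit"
    DISBENEFIT = "disbenefit"
    REVENUE = "revenue"
    REVENUE_EXPENSE = "revenue_expense"


#: Sign each flow contributes to the net social benefit.
NSB_SIGN: Mapping[Flow, int] = {
    Flow.COST: -1,
    Flow.BENEFIT: +1,
    Flow.DISBENEFIT: -1,
    Flow.REVENUE: +1,
    Flow.REVENUE_EXPENSE: -1,
}

#: The three reporting blocks of the summary table, as signed flow groups.
#: "benefit" nets disbenefits off against benefits, "revenue" nets the
#: retail outflows off against gross sales.
FLOW_GROUPS: Mapping[str, Mapping[Flow, int]] = {
    "cost": {Flow.COST: +1},
    "benefit": {Flow.BENEFIT: +1, Flow.DISBENEFIT: -1},
    "revenue": {Flow.REVENUE: +1, Flow.REVENUE_EXPENSE: -1},
}

_COLUMNS = ["name", "policy", "category", "flow", "main", "low", "high", "include_in_nsb"]


@dataclass(frozen=True)
class ComponentEstimate:
    """One ledger entry: a named cost or benefit with its uncertainty range.

    ``main``, ``low`` and ``high`` are positive magnitudes in millions of
    2007 AUD; direction comes from ``flow``.  ``low <= high`` is enforced
    strictly; ``main`` may sit outside [low, high] by at most
    :data:`ROUNDING_SLACK` to accommodate printed rounding.
    """

    name: str
    policy: Policy
    category: Category
    flow: Flow
    main: float
    low: float
    high: float
    include_in_nsb: bool = True

    def __post_init__(self) -> None:
        for field in ("main", "low", "high"):
            value = getattr(self, field)
            if not math.isfinite(value):
                raise LedgerValidationError(f"component {self.name!r}: {field} is not finite")
            if value < 0:
                raise LedgerValidationError(
                    f"component {self.name!r}: {field}={value} is negative; "
                    "store magnitudes positive and carry the sign in `flow`"
                )
        if self.low > self.high:
            raise LedgerValidationError(
                f"component {self.name!r}: low={self.low} > high={self.high}"
            )
        if self.main < self.low - ROUNDING_SLACK or self.main > self.high + ROUNDING_SLACK:
            raise LedgerValidationError(
                f"component {self.name!r}: main={self.main} outside "
                f"[{self.low}, {self.high}] by more than the rounding slack"
            )

    @property
    def nsb_sign(self) -> int:
        return NSB_SIGN[self.flow]

    @property
    def signed_main(self) -> float:
        """Main estimate with its NSB sign applied."""
        return self.nsb_sign * self.main

    def scaled(self, factor: float) -> "ComponentEstimate":
        """Return a copy with main, low and high scaled by ``factor >= 0``."""
        if factor < 0:
            raise LedgerValidationError(
                f"component {self.name!r}: scaling factor {factor} is negative"
            )
        return replace(self, main=self.main * factor, low=self.low * factor, high=self.high * factor)


@dataclass(frozen=True)
class Ledger:
    """Ordered, validated collection of :class:`ComponentEstimate` rows."""

    components: tuple[ComponentEstimate, ...]
    currency_year: int = CURRENCY_YEAR
    units: str = UNITS

    def __post_init__(self) -> None:
        seen: set[tuple[str, Policy]] = set()
        for c in self.components:
            key = (c.name, c.policy)
            if key in seen:
                raise LedgerValidationError(
                    f"duplicate component {c.name!r} for policy {c.policy.value!r}"
                )
            seen.add(key)

    def __iter__(self) -> Iterator[ComponentEstimate]:
        return iter(self.components)

    def __len__(self) -> int:
        return len(self.components)

    def names(self) -> list[str]:
        return [c.name for c in self.components]

    def get(self, name: str) -> ComponentEstimate:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(
            f"unknown component {name!r}; valid names: {', '.join(self.names())}"
        )

    def filter(
        self,
        policy: Union[Policy, str, None] = None,
        flow: Union[Flow, str, None] = None,
    ) -> "Ledger":
        """Components applicable to ``policy`` (shared ``both`` rows included)."""
        out: Iterable[ComponentEstimate] = self.components
        if policy is not None:
            policy = Policy(policy)
            if policy is Policy.BOTH:
                out = [c for c in out if c.policy is Policy.BOTH]
            else:
                out = [c for c in out if c.policy in (policy, Policy.BOTH)]
        if flow is not None:
            flow = Flow(flow)
            out = [c for c in out if c.flow is flow]
        return Ledger(tuple(out), self.currency_year, self.units)


def apply_default_range(main: float) -> tuple[float, float]:
    """Default +/-20% uncertainty band around ``main``.

    Used where no source-specific range exists.  The pair is returned in
    (low, high) order whatever the sign of ``main``, so it stays valid for
    signed working values as well as positive stored magnitudes.
    """
    if not math.isfinite(main):
        raise ValueError("main must be finite")
    a, b = 0.8 * main, 1.2 * main
    return (a, b) if a <= b else (b, a)


def read_ledger(path: Union[str, Path]) -> Ledger:
    """Read a component ledger from a delimited table.

    The file must be UTF-8, comma-delimited, with a header row naming the
    columns ``name, policy, category, flow, main, low, high,
    include_in_nsb`` and "." as the decimal mark.

    Raises
    ------
    LedgerSchemaError
        if a required column is missing.
    LedgerValidationError
        if any row violates a component invariant (the offending row is
        named in the message).
    """
    frame = pd.read_csv(path)
    missing = [col for col in _COLUMNS if col not in frame.columns]
    if missing:
        raise LedgerSchemaError(
            f"ledger file {path!s} is missing column(s): {', '.join(missing)}"
        )
    components = []
    for row in frame.itertuples(index=False):
        components.append(
            ComponentEstimate(
                name=str(row.name),
                policy=Policy(row.policy),
                category=Category(row.category),
                flow=Flow(row.flow),
                main=float(row.main),
                low=float(row.low),
                high=float(row.high),
                include_in_nsb=_parse_bool(row.include_in_nsb, str(row.name)),
            )
        )
    return Ledger(tuple(components))


def _parse_bool(value: object, name: str) -> bool:
    if isinstance(value, (bool,)) or value in (0, 1):
        return bool(value)
    text = str(value).strip().lower()
    if text in ("true", "1", "yes"):
        return True
    if text in ("false", "0", "no"):
        return False
    raise LedgerValidationError(f"component {name!r}: include_in_nsb={value!r} is not boolean")


def write_ledger(ledger: Ledger, path: Union[str, Path]) -> None:
    """Write ``ledger`` back to a delimited table, round-trippable at full
    stored precision."""
    frame = pd.DataFrame(
        {
            "name": [c.name for c in ledger],
            "policy": [c.policy.value for c in ledger],
            "category": [c.category.value for c in ledger],
            "flow": [c.flow.value for c in ledger],
            "main": [repr(c.main) for c in ledger],
            "low": [repr(c.low) for c in ledger],
            "high": [repr(c.high) for c in ledger],
            "include_in_nsb": [c.include_in_nsb for c in ledger],
        }
    )
    frame.to_csv(path, index=False)


def sum_flows(
    ledger: Ledger,
    policy: Union[Policy, str],
    flow: Union[Flow, str],
) -> float:
    """Signed block total of main estimates, in millions of 2007 AUD.

    ``flow`` may be one of the three reporting groups ``"cost"``,
    ``"benefit"`` (benefits net of disbenefits) or ``"revenue"`` (gross
    sales net of grower payments and shop operation), or a specific
    :class:`Flow` member for the raw unsigned magnitude sum of that flow
    alone.  An empty selection sums to 0.
    """
    policy = Policy(policy)
    selected = ledger.filter(policy=policy)
    if isinstance(flow, str) and flow in FLOW_GROUPS:
        signs = FLOW_GROUPS[flow]
        return float(sum(signs[c.flow] * c.main for c in selected if c.flow in signs))
    flow = Flow(flow)
    return float(sum(c.main for c in selected if c.flow is flow))


def _load_packaged(filename: str) -> Ledger:
    source = resources.files("cannabis_cba.data").joinpath(filename)
    with resources.as_file(source) as path:
        return read_ledger(path)


def load_status_quo() -> Ledger:
    """Packaged ledger for the status-quo (prohibition with diversion) policy."""
    return _load_packaged("status_quo.csv")


def load_legalised_regulated() -> Ledger:
    """Packaged ledger for the legalised-regulated policy, including the
    retail revenue block (excluded from the NSB unless requested)."""
    return _load_packaged("legalised_regulated.csv")
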