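"""Net-social-benefit aggregation, Monte Carlo propagation and scenarios.

The net social benefit (NSB) of a policy is the sum of its valued benefits
minus the sum of its valued costs.  Uncertainty is propagated by Monte
Carlo: each ledger component is drawn independently from a normal
distribution parameterised by its (low, high) range, the per-draw NSB is
the signed sum of the draws, and the result is summarised by the mean and
the empirical 5th/95th percentiles.

Under the default ``sd_rule`` (``"central90"``) the range is read as a
central 90% interval and fully determines the sampling normal: mean at the
interval centre ``(low+high)/2``, standard deviation
``(high-low)/(2 * 1.6449)``.  The alternative rule ``"main"`` keeps the
same standard deviation but centres the normal on the main estimate.  For
a symmetric range the two coincide; a degenerate range (low == main ==
high) collapses to the main estimate exactly under either rule.

Government revenue is a transfer payment and is excluded unless
``include_revenue`` is set, in which case the retail rows (gross sales,
grower payments, shop operating) are sampled from their own ranges like
any other component.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence, Union

import numpy as np
from scipy import stats

from .consumption import elasticity_scenario
from .ledger import ComponentEstimate, Flow, Ledger, Policy

__all__ = [
    "Z90",
    "MonteCarloConfig",
    "NSBResult",
    "ScenarioSpec",
    "component_normal",
    "sample_component",
    "point_nsb",
    "run_monte_carlo",
    "apply_scenario",
    "point_scenario_nsb",
    "run_scenario",
    "one_way_sensitivity",
]

#: 95th percentile of the standard normal: half-width of a central 90%
#: interval in standard deviations.
Z90: float = float(stats.norm.ppf(0.95))

_SD_RULES = ("central90", "main")


@dataclass(frozen=True)
class MonteCarloConfig:
    """Simulation settings; defaults follow the published protocol
    (normal draws, 1000 repetitions, 5th/95th percentiles)."""

    repetitions: int = 1000
    percentiles: tuple[float, float] = (5.0, 95.0)
    seed: int = 20074
    sd_rule: str = "central90"
    truncate_at_zero: bool = False

    def __post_init__(self) -> None:
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")
        lo, hi = self.percentiles
        if not (0.0 < lo < hi < 100.0):
            raise ValueError("percentiles must be strictly increasing within (0, 100)")
        if self.sd_rule not in _SD_RULES:
            raise ValueError(f"sd_rule must be one of {_SD_RULES}")


@dataclass(frozen=True)
class NSBResult:
    """Monte Carlo NSB summary with the per-repetition trace."""

    policy: Policy
    include_revenue: bool
    mean: float
    p5: float
    p95: float
    draws: np.ndarray

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "incl. revenue" if self.include_revenue else "excl. revenue"
        return (
            f"NSB[{self.policy.value}, {tag}] mean {self.mean:.1f}m "
            f"({self.p5:.1f} to {self.p95:.1f})"
        )


@dataclass(frozen=True)
class ScenarioSpec:
    """Declarative modification of a ledger before evaluation.

    ``component_scalings`` multiplies a component's (main, low, high) by a
    non-negative factor (0 removes it); ``point_overrides`` replaces a
    main estimate by its own low or high bound; ``elasticity`` applies a
    constant-price quantity response ``(price_change, elasticity)`` to the
    wellbeing component; ``include_revenue`` switches the retail revenue
    block into the NSB.
    """

    component_scalings: Mapping[str, float] = field(default_factory=dict)
    point_overrides: Mapping[str, str] = field(default_factory=dict)
    elasticity: Optional[tuple[float, float]] = None
    include_revenue: bool = False

    def __post_init__(self) -> None:
        for name, factor in self.component_scalings.items():
            if factor < 0:
                raise ValueError(f"scaling for {name!r} must be non-negative")
        for name, which in self.point_overrides.items():
            if which not in ("use_low", "use_high"):
                raise ValueError(
                    f"point override for {name!r} must be 'use_low' or 'use_high'"
                )


def component_normal(
    component: ComponentEstimate, sd_rule: str = "central90"
) -> tuple[float, float]:
    """(mean, sd) of the sampling normal for one component's magnitude."""
    sd = (component.high - component.low) / (2.0 * Z90)
    if sd_rule == "central90":
        mean = 0.5 * (component.low + component.high)
    elif sd_rule == "main":
        mean = component.main
    else:
        raise ValueError(f"sd_rule must be one of {_SD_RULES}")
    return mean, sd


def sample_component(
    component: ComponentEstimate,
    config: MonteCarloConfig,
    rng: np.random.Generator,
) -> float:
    """One draw of a component's magnitude (unsigned, millions AUD).

    A degenerate range returns the main estimate exactly, without
    consuming randomness.
    """
    mean, sd = component_normal(component, config.sd_rule)
    if sd == 0.0:
        return component.main if component.low == component.high == component.main else mean
    draw = mean + sd * rng.standard_normal()
    if config.truncate_at_zero:
        draw = max(draw, 0.0)
    return float(draw)


def _included(ledger: Ledger, policy: Policy, include_revenue: bool):
    components = ledger.filter(policy=policy).components
    if not components and policy not in {c.policy for c in ledger} and len(ledger) > 0:
        raise ValueError(f"ledger has no components for policy {policy.value!r}")
    out = []
    for c in components:
        if c.include_in_nsb:
            out.append(c)
        elif include_revenue and c.flow in (Flow.REVENUE, Flow.REVENUE_EXPENSE):
            out.append(c)
    return out


def point_nsb(
    ledger: Ledger,
    policy: Union[Policy, str],
    include_revenue: bool = False,
) -> float:
    """Deterministic NSB on main estimates: benefits minus costs, in
    millions AUD, plus net revenue when ``include_revenue`` is set."""
    policy = Policy(policy)
    return float(
        sum(c.signed_main for c in _included(ledger, policy, include_revenue))
    )


def run_monte_carlo(
    ledger: Ledger,
    policy: Union[Policy, str],
    config: MonteCarloConfig = MonteCarloConfig(),
    include_revenue: bool = False,
) -> NSBResult:
    """Monte Carlo NSB for one policy.

    Components are drawn independently (the analysis states no correlation
    structure), each as a vector of ``repetitions`` normal variates; the
    per-draw NSB is the signed sum.  Results are bit-reproducible for a
    given seed and configuration: components consume randomness in ledger
    order, one vector each, so scaling or overriding a component leaves
    every other component's draws unchanged.
    """
    policy = Policy(policy)
    rng = np.random.default_rng(config.seed)
    draws = np.zeros(config.repetitions)
    for component in _included(ledger, policy, include_revenue):
        mean, sd = component_normal(component, config.sd_rule)
        values = mean + sd * rng.standard_normal(config.repetitions)
        if config.truncate_at_zero:
            np.clip(values, 0.0, None, out=values)
        draws += component.nsb_sign * values
    lo, hi = config.percentiles
    p5, p95 = np.percentile(draws, [lo, hi])  # linear interpolation on order stats
    if draws.size and np.all(draws == draws[0]):
        # constant trace (all ranges degenerate): the mean is the constant
        # itself, without summation rounding
        mean = float(draws[0])
    else:
        mean = float(draws.mean())
    return NSBResult(
        policy=policy,
        include_revenue=include_revenue,
        mean=mean,
        p5=float(p5),
        p95=float(p95),
        draws=draws,
    )


def apply_scenario(ledger: Ledger, spec: ScenarioSpec) -> Ledger:
    """Return a copy of ``ledger`` with the scenario's modifications applied.

    Unknown component names raise a ``KeyError`` listing the valid names.
    The component order is preserved, which keeps scenario runs draw-for-
    draw comparable with the unmodified simulation at equal seed.
    """
    names = set(ledger.names())
    referenced = set(spec.component_scalings) | set(spec.point_overrides)
    if spec.elasticity is not None:
        referenced.add("wellbeing")
    unknown = referenced - names
    if unknown:
        raise KeyError(
            f"unknown component(s) {sorted(unknown)}; valid names: "
            f"{', '.join(sorted(names))}"
        )
    components = []
    for c in ledger:
        if c.name in spec.point_overrides:
            bound = c.low if spec.point_overrides[c.name] == "use_low" else c.high
            c = replace(c, main=bound)
        if c.name in spec.component_scalings:
            c = c.scaled(spec.component_scalings[c.name])
        if spec.elasticity is not None and c.name == "wellbeing":
            price_change, elasticity = spec.elasticity
            factor = elasticity_scenario(1.0, price_change, elasticity)
            c = c.scaled(factor)
        components.append(c)
    return Ledger(tuple(components), ledger.currency_year, ledger.units)


def point_scenario_nsb(
    ledger: Ledger, policy: Union[Policy, str], spec: ScenarioSpec
) -> float:
    """Deterministic NSB of a scenario (main estimates only)."""
    return point_nsb(apply_scenario(ledger, spec), policy, spec.include_revenue)


def run_scenario(
    ledger: Ledger,
    policy: Union[Policy, str],
    spec: ScenarioSpec,
    config: MonteCarloConfig = MonteCarloConfig(),
) -> NSBResult:
    """Monte Carlo NSB of a modified ledger.

    All components not named by the scenario are held at their original
    parameterisation; with the identity scenario the result equals
    :func:`run_monte_carlo` draw for draw at equal seed.
    """
    return run_monte_carlo(
        apply_scenario(ledger, spec), policy, config, spec.include_revenue
    )


def one_way_sensitivity(
    ledger: Ledger,
    policy: Union[Policy, str],
    include_revenue: bool = False,
    components: Optional[Sequence[str]] = None,
):
    """One-at-a-time low/high sweep on the deterministic NSB.

    For each component, the main estimate is replaced by its low and then
    its high bound while everything else is held constant.  Returns a
    pandas DataFrame with the resulting NSB and its change relative to the
    base point NSB, in millions AUD.
    """
    import pandas as pd

    policy = Policy(policy)
    base = point_nsb(ledger, policy, include_revenue)
    rows = []
    selected = ledger.filter(policy=policy)
    for c in selected:
        if components is not None and c.name not in components:
            continue
        if not c.include_in_nsb and not include_revenue:
            continue
        for which, label in (("use_low", "low"), ("use_high", "high")):
            spec = ScenarioSpec(point_overrides={c.name: which}, include_revenue=include_revenue)
            value = point_scenario_nsb(ledger, policy, spec)
            rows.append(
                {
                    "component": c.name,
                    "bound": label,
                    "nsb": value,
                    "delta_nsb": value - base,
                }
            )
    return pd.DataFrame(rows)
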