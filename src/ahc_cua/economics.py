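"""Intervention costing, cross-condition aggregation and cost-effectiveness
metrics (ICER, net monetary benefit, acceptability curves)."""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .conditions import ALL_CONDITIONS, ConditionResult, ModelContext, incremental_condition


class EconomicsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# intervention costing

INTERVENTION_ROLES = ("gp", "nurse", "support_worker", "social_worker")


def intervention_components(pm: Mapping[str, float]) -> tuple[tuple[str, float, float], ...]:
    """(role, minutes, unit cost per hour) tuples from the parameter map."""
    return tuple(
        (role, pm[f"intervention.{role}.minutes"], pm[f"intervention.{role}.rate_per_hour"])
        for role in INTERVENTION_ROLES
    )


def intervention_yearly_cost(components: Iterable[tuple[str, float, float]]) -> float:
    """Cost of one annual health check.

    Each component's cost (minutes/60 x hourly rate) is rounded to the
    nearest pound before summation, so the published per-person figure is
    reproduced exactly from its time-and-rate build-up.
    """
    total = 0.0
    for role, minutes, rate in components:
        if minutes < 0 or rate < 0:
            raise EconomicsError(f"negative quantity for component {role!r}")
        total += math.floor(minutes / 60.0 * rate + 0.5)
    return float(total)


def annuity_factor(survival_values: Sequence[float], rate: float) -> float:
    """Half-cycle-corrected discounted annuity of one pound per year alive."""
    S = np.asarray(survival_values, dtype=float)
    mid = 0.5 * (S[:-1] + S[1:])
    k = np.arange(mid.size)
    return float(np.sum(mid / (1.0 + rate) ** k))


def intervention_cost_pv(
    yearly_cost: float, survival_values: Sequence[float], rate: float
) -> float:
    """Present value of the yearly check paid while alive, half-cycle
    corrected consistently with the cohort engine, discounted to the base
    age."""
    return yearly_cost * annuity_factor(survival_values, rate)


# ---------------------------------------------------------------------------
# aggregation

@dataclass(frozen=True)
class StrategyResult:
    """Aggregated incremental result of the AHC strategy vs standard care."""

    intervention_pv: float
    per_condition: tuple[ConditionResult, ...]

    @property
    def inc_cost_total(self) -> float:
        return self.intervention_pv + sum(c.inc_cost for c in self.per_condition)

    @property
    def inc_qaly_total(self) -> float:
        return sum(c.inc_qaly for c in self.per_condition)


def aggregate_strategy(
    condition_results: Iterable[ConditionResult], intervention_pv: float
) -> StrategyResult:
    results = tuple(condition_results)
    tags = [c.condition for c in results]
    if len(set(tags)) != len(tags):
        raise EconomicsError(f"duplicate condition tags in {tags}")
    return StrategyResult(intervention_pv, tuple(sorted(results, key=lambda c: c.condition)))


def evaluate_strategy(pm: Mapping[str, float], ctx: ModelContext) -> StrategyResult:
    """Full pipeline for one parameter map: all condition models under both
    arms plus the discounted intervention annuity."""
    results = [incremental_condition(c, pm, ctx) for c in ALL_CONDITIONS]
    pv = intervention_cost_pv(
        pm["intervention.yearly_cost"], ctx.survival(ctx.base_age), ctx.discount_rate
    )
    return aggregate_strategy(results, pv)


# ---------------------------------------------------------------------------
# cost-effectiveness metrics

@dataclass(frozen=True)
class IcerResult:
    value: float  # nan when the ratio is undefined
    flag: str  # "", "dominant", "dominated", "undefined", "less_costly_less_effective"


def icer(inc_cost: float, inc_qaly: float) -> IcerResult:
    """Incremental cost-effectiveness ratio with dominance flags (flags, not
    exceptions, so sensitivity-analysis draws never abort a run)."""
    if inc_qaly > 0:
        value = inc_cost / inc_qaly
        return IcerResult(value, "dominant" if inc_cost < 0 else "")
    if inc_cost == 0 and inc_qaly == 0:
        return IcerResult(math.nan, "undefined")
    if inc_cost > 0:
        return IcerResult(math.nan, "dominated")
    return IcerResult(math.nan, "less_costly_less_effective")


def nmb(inc_cost: float, inc_qaly: float, threshold: float) -> float:
    """Net monetary benefit at willingness-to-pay ``threshold`` per QALY."""
    if threshold < 0:
        raise EconomicsError("threshold must be >= 0")
    return threshold * inc_qaly - inc_cost


def ceac(
    draws: Sequence[tuple[float, float]], thresholds: Sequence[float]
) -> list[tuple[float, float]]:
    """Cost-effectiveness acceptability curve: fraction of (inc_cost,
    inc_qaly) draws with positive net monetary benefit at each threshold."""
    arr = np.asarray(draws, dtype=float)
    if arr.size == 0:
        raise EconomicsError("empty draw set")
    cost, qaly = arr[:, 0], arr[:, 1]
    return [
        (float(t), float(np.mean(t * qaly - cost > 0))) for t in thresholds
    ]
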