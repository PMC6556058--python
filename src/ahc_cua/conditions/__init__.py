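"""Condition-specific decision models.

Five conditions are full state-transition models (hypertension, glaucoma,
osteoporosis, bowel and breast screening); three are screening/treatment
cascades whose published evidence arrives as lifetime cost and QALY deltas
assigned at the cycle of benefit (diabetes, cataract, hearing). Each model is
evaluated under both strategy arms with the same parameter draw and reports
the incremental present values, discounted to the common base age of 40.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from ..markov import MarkovModel, present_value, run_cohort
from ..mortality import LifeTable, adjust_id_mortality, survival_curve

ARMS = ("ahc", "standard")

STATE_MODEL_CONDITIONS = (
    "hypertension",
    "glaucoma",
    "osteoporosis",
    "bowel_screening",
    "breast_screening",
)
CASCADE_CONDITIONS = ("diabetes", "cataract", "hearing")
ALL_CONDITIONS = STATE_MODEL_CONDITIONS + CASCADE_CONDITIONS

START_AGES = {
    "osteoporosis": 50,
    "bowel_screening": 60,
    "breast_screening": 50,
}

#: parameter pairs that differ between arms (AHC name, standard-care name)
ARM_EFFECT_PAIRS = (
    ("hypertension.p_identified_managed.ahc", "hypertension.p_identified_managed.standard"),
    ("diabetes.p_managed.ahc", "diabetes.p_managed.standard"),
    ("breast.participation.ahc", "breast.participation.standard"),
    ("osteoporosis.p_investigated.ahc", "osteoporosis.p_investigated.standard"),
    ("eye.p_referred.ahc", "eye.p_referred.standard"),
    ("hearing.p_referred.ahc", "hearing.p_referred.standard"),
)
#: additive arm effects that vanish at zero
ARM_EFFECT_DELTAS = ("bowel.participation_delta_ahc",)


class ConditionError(ValueError):
    pass


def banded(pm: Mapping[str, float], base: str, age: int) -> float:
    """Age-banded lookup on the 40-49 / 50-64 / 65+ incidence bands."""
    if age < 50:
        suffix = "40_49"
    elif age < 65:
        suffix = "50_64"
    else:
        suffix = "65_plus"
    return pm[f"{base}.{suffix}"]


def banded_rr(pm: Mapping[str, float], base: str, age: int) -> float:
    """Age-banded lookup on the 40-59 / 60+ relative-risk bands."""
    return pm[f"{base}.40_59"] if age < 60 else pm[f"{base}.60_plus"]


@dataclass(frozen=True)
class ModelContext:
    """Shared run context: the ID-adjusted life table, discounting and the
    common time origin every model discounts to."""

    life_table: LifeTable
    discount_rate: float
    base_age: int = 40
    age_cap: int = 100

    @classmethod
    def default(cls, metadata: Mapping | None = None, life_table: LifeTable | None = None):
        from ..synthetic import gompertz_life_table

        md = dict(metadata or {})
        table = life_table if life_table is not None else gompertz_life_table()
        mult = float(md.get("id_mortality_multiplier", 3.0))
        adjusted = adjust_id_mortality(table, mult)
        return cls(
            life_table=adjusted,
            discount_rate=float(md.get("discount_rate", 0.035)),
            base_age=int(md.get("base_age", 40)),
            age_cap=int(md.get("age_cap", 100)),
        )

    def qx_at(self, age: int) -> float:
        return self.life_table.q_at(age)

    def survival(self, start_age: int) -> np.ndarray:
        return survival_curve(self.life_table, start_age, self.age_cap).values

    def entry_survival(self, start_age: int) -> float:
        """Probability of surviving from the base age to a model's start age."""
        if start_age == self.base_age:
            return 1.0
        return float(self.survival(self.base_age)[start_age - self.base_age])


@dataclass(frozen=True)
class ConditionResult:
    """Discounted lifetime cost and QALY contribution of one condition."""

    condition: str
    pv_cost: dict
    pv_qaly: dict

    @property
    def inc_cost(self) -> float:
        return self.pv_cost["ahc"] - self.pv_cost["standard"]

    @property
    def inc_qaly(self) -> float:
        return self.pv_qaly["ahc"] - self.pv_qaly["standard"]


def build_state_model(
    condition: str, arm: str, parameter_map: Mapping[str, float], ctx: ModelContext
) -> MarkovModel:
    """Construct the Markov model for one state-transition condition/arm."""
    from . import state_models

    if arm not in ARMS:
        raise ConditionError(f"unknown arm {arm!r}")
    try:
        builder = state_models.BUILDERS[condition]
    except KeyError:
        raise ConditionError(f"unknown state-model condition {condition!r}") from None
    return builder(arm, parameter_map, ctx)


def evaluate_cascade_condition(
    condition: str, parameter_map: Mapping[str, float], ctx: ModelContext
) -> ConditionResult:
    """Evaluate a cascade condition (both arms, same draw)."""
    from . import cascades

    try:
        fn = cascades.EVALUATORS[condition]
    except KeyError:
        raise ConditionError(f"unknown cascade condition {condition!r}") from None
    return fn(parameter_map, ctx)


def incremental_condition(
    condition: str, parameter_map: Mapping[str, float], ctx: ModelContext
) -> ConditionResult:
    """Run both strategy arms with the same parameter draw and return the
    per-arm present values (common-random-numbers contract)."""
    if condition in CASCADE_CONDITIONS:
        return evaluate_cascade_condition(condition, parameter_map, ctx)
    if condition not in STATE_MODEL_CONDITIONS:
        raise ConditionError(f"unknown condition {condition!r}")
    start_age = START_AGES.get(condition, ctx.base_age)
    offset = start_age - ctx.base_age
    entry = ctx.entry_survival(start_age)
    scale = entry
    if condition == "breast_screening":
        scale *= parameter_map["breast.female_proportion"]
    pv_cost, pv_qaly = {}, {}
    for arm in ARMS:
        model = build_state_model(condition, arm, parameter_map, ctx)
        trace = run_cohort(model, parameter_map, ctx.age_cap)
        pv_cost[arm] = scale * present_value(trace.cost_stream, ctx.discount_rate, offset)
        pv_qaly[arm] = scale * present_value(trace.qaly_stream, ctx.discount_rate, offset)
    return ConditionResult(condition, pv_cost, pv_qaly)


def required_parameters(condition: str) -> tuple[str, ...]:
    """Every parameter name a condition model reads (completeness checks)."""
    from . import cascades, state_models

    table = {**state_models.REQUIRED, **cascades.REQUIRED}
    try:
        return table[condition]
    except KeyError:
        raise ConditionError(f"unknown condition {condition!r}") from None
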