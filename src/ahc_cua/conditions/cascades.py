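"""Cascade conditions: diabetes, cataract, hearing.

For these conditions the published evidence arrives as probability cascades
plus lifetime (present-value) cost and QALY deltas, so rather than tracking
disease states the models propagate survival-weighted incident (or
at-risk) fractions and assign the deltas at the cycle of benefit,
discounting to the common base age of 40.

Only the components that differ between strategy arms are accrued; the
baseline quality of life of simply being alive cancels in the increment and
is therefore not carried (the state-transition models do carry it, because
there mortality itself differs between arms).
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from . import ConditionResult, ModelContext, banded

ARMS = ("ahc", "standard")


def _grid(ctx: ModelContext):
    """Ages, survival at cycle start and discount factors from the base age."""
    ages = np.arange(ctx.base_age, ctx.age_cap)
    S = ctx.survival(ctx.base_age)  # len = cycles + 1
    disc = (1.0 + ctx.discount_rate) ** (-np.arange(ages.size))
    return ages, S, disc


def diabetes(pm: Mapping[str, float], ctx: ModelContext) -> ConditionResult:
    """Closer monitoring of incident diabetes.

    Each newly incident case is 'managed' with an arm-specific probability;
    managed cases receive the published lifetime cost and QALY deltas for
    controlled versus uncontrolled glucose, mixed over the obesity strata
    (overweight treated with metformin, non-overweight with insulin), once
    at incidence. Incidence is reduced by the configurable overlap share
    already attributed to the hypertension model.
    """
    ages, S, disc = _grid(ctx)
    inc = np.array([banded(pm, "diabetes.incidence", a) for a in ages])
    inc = inc * (1.0 - pm["diabetes.overlap_adjustment"])
    free = np.concatenate([[1.0], np.cumprod(1.0 - inc)])[:-1]  # never-diabetic share
    events = S[:-1] * free * inc
    ob = pm["diabetes.obesity_proportion"]
    d_cost = (
        ob * pm["diabetes.cost.delta_managed_overweight"]
        + (1.0 - ob) * pm["diabetes.cost.delta_managed_non_overweight"]
    )
    d_qaly = (
        ob * pm["diabetes.qaly.delta_managed_overweight"]
        + (1.0 - ob) * pm["diabetes.qaly.delta_managed_non_overweight"]
    )
    pv_cost, pv_qaly = {}, {}
    for arm in ARMS:
        p = pm[f"diabetes.p_managed.{arm}"]
        pv_cost[arm] = float(np.sum(events * p * d_cost * disc))
        pv_qaly[arm] = float(np.sum(events * p * d_qaly * disc))
    return ConditionResult("diabetes", pv_cost, pv_qaly)


REQUIRED_DIA = (
    "diabetes.incidence.40_49", "diabetes.incidence.50_64", "diabetes.incidence.65_plus",
    "diabetes.obesity_proportion", "diabetes.overlap_adjustment",
    "diabetes.p_managed.ahc", "diabetes.p_managed.standard",
    "diabetes.cost.delta_managed_overweight", "diabetes.cost.delta_managed_non_overweight",
    "diabetes.qaly.delta_managed_overweight", "diabetes.qaly.delta_managed_non_overweight",
)


def cataract(pm: Mapping[str, float], ctx: ModelContext) -> ConditionResult:
    """Cataract identification through eye exams.

    Incident cataract is referred with an arm-specific probability at the
    incidence cycle; referral incurs the optometrist test, a diagnosis test
    for the cases with findings (glasses or surgery), and for the surgical
    fraction the lifetime surgery cost together with its present-value QALY
    gain, assigned once.
    """
    ages, S, disc = _grid(ctx)
    inc = np.array([banded(pm, "cataract.incidence", a) for a in ages])
    free = np.concatenate([[1.0], np.cumprod(1.0 - inc)])[:-1]
    events = S[:-1] * free * inc
    p_sur = pm["cataract.p_surgery"]
    p_gla = pm["cataract.p_glasses"]
    cost_per_referral = (
        pm["eye.cost.optometrist_test"]
        + (p_gla + p_sur) * pm["eye.cost.diagnosis_test"]
        + p_sur * pm["cataract.cost.surgery_lifetime"]
    )
    qaly_per_referral = p_sur * pm["cataract.qaly.gain_surgery"]
    pv_cost, pv_qaly = {}, {}
    for arm in ARMS:
        ref = pm[f"eye.p_referred.{arm}"]
        pv_cost[arm] = float(np.sum(events * ref * cost_per_referral * disc))
        pv_qaly[arm] = float(np.sum(events * ref * qaly_per_referral * disc))
    return ConditionResult("cataract", pv_cost, pv_qaly)


REQUIRED_CAT = (
    "cataract.incidence.40_49", "cataract.incidence.50_64", "cataract.incidence.65_plus",
    "eye.p_referred.ahc", "eye.p_referred.standard",
    "cataract.p_glasses", "cataract.p_surgery",
    "eye.cost.optometrist_test", "eye.cost.diagnosis_test",
    "cataract.cost.surgery_lifetime", "cataract.qaly.gain_surgery",
)


def hearing(pm: Mapping[str, float], ctx: ModelContext) -> ConditionResult:
    """Hearing problems: wax removal and hearing-aid provision.

    Every cycle, a share of the unaddressed population presents a hearing
    problem. Referred wax cases get removal (cost plus a one-off utility
    gain) and leave the at-risk pool; referred non-wax cases who attend the
    specialist either become aid users (initial cost, then annual follow-on
    cost and an annual utility gain while alive) or leave the pool addressed.
    Non-referred and non-attending people stay at risk, so the standard-care
    arm catches up over time -- the arms differ in *when* problems are
    addressed.
    """
    ages, S, disc = _grid(ctx)
    n = ages.size
    h = pm["hearing.p_problem_annual"]
    wax = pm["hearing.p_wax"]
    spec_branch = 1.0 - wax
    att = pm["hearing.p_attend_specialist"]
    need = pm["hearing.p_aid_required"]
    acc = pm["hearing.p_aid_accepted"]
    c_event_common = wax * pm["hearing.cost.wax_removal"] + spec_branch * att * (
        pm["hearing.cost.specialist_assessment"]
        + need * pm["hearing.cost.aid_assessment"]
        + need * acc * pm["hearing.cost.aid_initial"]
    )
    d_wax = pm["hearing.utility.gain_wax"]
    d_aid = pm["hearing.utility.gain_aid"]
    c_follow = pm["hearing.cost.aid_followon_annual"]

    pv_cost, pv_qaly = {}, {}
    for arm in ARMS:
        ref = pm[f"hearing.p_referred.{arm}"]
        resolve = ref * (wax + spec_branch * att)
        aided_inflow = ref * spec_branch * att * need * acc
        at_risk, aided = 1.0, 0.0
        cost = np.zeros(n)
        qaly = np.zeros(n)
        for k in range(n):
            events = S[k] * at_risk * h
            cost[k] = events * ref * c_event_common
            qaly[k] = events * ref * wax * d_wax
            aided_next = aided + at_risk * h * aided_inflow
            mid_aided = 0.5 * (S[k] * aided + S[k + 1] * aided_next)
            cost[k] += mid_aided * c_follow
            qaly[k] += mid_aided * d_aid
            at_risk *= 1.0 - h * resolve
            aided = aided_next
        pv_cost[arm] = float(np.sum(cost * disc))
        pv_qaly[arm] = float(np.sum(qaly * disc))
    return ConditionResult("hearing", pv_cost, pv_qaly)


REQUIRED_HEA = (
    "hearing.p_problem_annual", "hearing.p_referred.ahc", "hearing.p_referred.standard",
    "hearing.p_wax", "hearing.p_attend_specialist", "hearing.p_aid_required",
    "hearing.p_aid_accepted",
    "hearing.cost.wax_removal", "hearing.cost.specialist_assessment",
    "hearing.cost.aid_assessment", "hearing.cost.aid_initial",
    "hearing.cost.aid_followon_annual",
    "hearing.utility.gain_wax", "hearing.utility.gain_aid",
)


EVALUATORS = {"diabetes": diabetes, "cataract": cataract, "hearing": hearing}

REQUIRED = {"diabetes": REQUIRED_DIA, "cataract": REQUIRED_CAT, "hearing": REQUIRED_HEA}
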