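"""State-transition condition models.

Shared conventions. Competing risks within a cycle are ordered death →
disease event → identification; residual probability is assigned explicitly
to the stay state so row sums are exact by construction. Diagnosis and test
costs are one-off transition rewards; treatment, management and sequela
maintenance are annual state rewards; first-year/subsequent-year cost pairs
use one-cycle tunnel states. Condition-specific death acts on top of
background mortality from the ID-adjusted life table.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from ..markov import MarkovModel
from . import ModelContext, banded, banded_rr

Arm = str


def _const(vec: np.ndarray):
    return lambda age: vec


# ---------------------------------------------------------------------------
# hypertension (start age 40)

HT_STATES = (
    "Well",
    "HT-Undetected",
    "HT-Managed",
    "HT-Unmanaged",
    "Stroke-Y1",
    "Post-Stroke",
    "CHD-Y1",
    "Post-CHD",
    "Dead",
)


def hypertension(arm: Arm, pm: Mapping[str, float], ctx: ModelContext) -> MarkovModel:
    """High blood pressure with stroke and coronary heart disease sequelae.

    New hypertensives are identified-and-managed with an arm-specific
    probability times treatment adherence; the undetected pool is re-screened
    every cycle. Managed patients carry age-banded relative risks of stroke,
    CHD and death versus unmanaged; event risks for hypertensives are the
    baseline population event rates times the published risk multipliers.
    """
    W, U, M, N, S1, S2, C1, C2, D = range(9)
    p_id = pm[f"hypertension.p_identified_managed.{arm}"]
    adh = pm["hypertension.adherence"]
    p_m, p_n = p_id * adh, p_id * (1.0 - adh)
    mult_s = pm["hypertension.rr_stroke_vs_baseline"]
    mult_c = pm["hypertension.rr_chd_vs_baseline"]

    def matrix(age: int, _pm) -> np.ndarray:
        q = ctx.qx_at(age)
        inc = banded(pm, "hypertension.incidence", age)
        s_un = min(1.0, banded(pm, "stroke.incidence", age) * mult_s)
        c_un = min(1.0, banded(pm, "chd.incidence", age) * mult_c)
        s_m = s_un * banded_rr(pm, "hypertension.rr_stroke_managed", age)
        c_m = c_un * banded_rr(pm, "hypertension.rr_chd_managed", age)
        q_m = min(1.0, q * banded_rr(pm, "hypertension.rr_death_managed", age))
        P = np.zeros((9, 9))
        live = 1.0 - q
        P[W, D] = q
        P[W, M] = live * inc * p_m
        P[W, N] = live * inc * p_n
        P[W, U] = live * inc * (1.0 - p_id)
        P[W, W] = live * (1.0 - inc)
        P[U, D] = q
        P[U, S1] = live * s_un
        P[U, C1] = live * c_un
        rest = live * (1.0 - s_un - c_un)
        P[U, M] = rest * p_m
        P[U, N] = rest * p_n
        P[U, U] = rest * (1.0 - p_id)
        P[N, D] = q
        P[N, S1] = live * s_un
        P[N, C1] = live * c_un
        P[N, N] = live * (1.0 - s_un - c_un)
        P[M, D] = q_m
        P[M, S1] = (1.0 - q_m) * s_m
        P[M, C1] = (1.0 - q_m) * c_m
        P[M, M] = (1.0 - q_m) * (1.0 - s_m - c_m)
        for a, b in ((S1, S2), (S2, S2), (C1, C2), (C2, C2)):
            P[a, D] = q
            P[a, b] = live
        P[D, D] = 1.0
        return P

    costs = np.zeros(9)
    costs[M] = pm["hypertension.cost.management_annual"]
    costs[S1] = pm["hypertension.cost.stroke_first_year"]
    costs[S2] = pm["hypertension.cost.stroke_subsequent"]
    costs[C1] = pm["hypertension.cost.chd_first_year"]
    costs[C2] = pm["hypertension.cost.chd_subsequent"]
    utils = np.zeros(9)
    utils[[W, U, M, N]] = pm["utility.well_baseline"]
    utils[[S1, S2]] = pm["utility.stroke"]
    utils[[C1, C2]] = pm["utility.chd"]
    tc = np.zeros((9, 9))
    c_diag = pm["hypertension.cost.diagnosis"]
    tc[W, M] = tc[W, N] = tc[U, M] = tc[U, N] = c_diag
    init = np.zeros(9)
    init[W] = 1.0
    return MarkovModel(
        HT_STATES, matrix, _const(costs), _const(utils),
        start_age=ctx.base_age, initial_occupancy=init,
        transition_costs=lambda age: tc,
    )


REQUIRED_HT = (
    "hypertension.incidence.40_49", "hypertension.incidence.50_64", "hypertension.incidence.65_plus",
    "stroke.incidence.40_49", "stroke.incidence.50_64", "stroke.incidence.65_plus",
    "chd.incidence.40_49", "chd.incidence.50_64", "chd.incidence.65_plus",
    "hypertension.p_identified_managed.ahc", "hypertension.p_identified_managed.standard",
    "hypertension.adherence",
    "hypertension.rr_stroke_managed.40_59", "hypertension.rr_stroke_managed.60_plus",
    "hypertension.rr_chd_managed.40_59", "hypertension.rr_chd_managed.60_plus",
    "hypertension.rr_death_managed.40_59", "hypertension.rr_death_managed.60_plus",
    "hypertension.rr_stroke_vs_baseline", "hypertension.rr_chd_vs_baseline",
    "hypertension.cost.diagnosis", "hypertension.cost.management_annual",
    "hypertension.cost.stroke_first_year", "hypertension.cost.stroke_subsequent",
    "hypertension.cost.chd_first_year", "hypertension.cost.chd_subsequent",
    "utility.well_baseline", "utility.stroke", "utility.chd",
)


# ---------------------------------------------------------------------------
# glaucoma (start age 40)

GLA_STATES = (
    "Well",
    "Undet-Mild", "Undet-Moderate", "Undet-Severe",
    "Treated-Mild", "Treated-Moderate", "Treated-Severe",
    "Untreated-Mild", "Untreated-Moderate", "Untreated-Severe",
    "Visual-Impairment",
    "Dead",
)


def glaucoma(arm: Arm, pm: Mapping[str, float], ctx: ModelContext) -> MarkovModel:
    """Open-angle glaucoma: detection via eye exam referral, then treated or
    untreated progression through mild/moderate/severe to visual impairment.

    Undetected disease progresses at untreated rates and is re-offered an eye
    exam every cycle; once referred, treatment adherence fixes the treated /
    untreated pathway. Referral incurs the optometrist test plus diagnosis
    cost once.
    """
    W = 0
    U1, U2, U3 = 1, 2, 3
    T1, T2, T3 = 4, 5, 6
    N1, N2, N3 = 7, 8, 9
    VI, D = 10, 11
    p_ref = pm[f"eye.p_referred.{arm}"]
    adh = pm["glaucoma.adherence"]
    pt = [pm[f"glaucoma.p_progress.{k}.treated"] for k in
          ("mild_to_moderate", "moderate_to_severe", "severe_to_vi")]
    pu = [pm[f"glaucoma.p_progress.{k}.untreated"] for k in
          ("mild_to_moderate", "moderate_to_severe", "severe_to_vi")]

    def matrix(age: int, _pm) -> np.ndarray:
        q = ctx.qx_at(age)
        inc = banded(pm, "glaucoma.incidence", age)
        live = 1.0 - q
        P = np.zeros((12, 12))
        P[W, D] = q
        P[W, U1] = live * inc
        P[W, W] = live * (1.0 - inc)
        for i, (u, t, n, prog, nxt) in enumerate(
            ((U1, T1, N1, pu[0], U2), (U2, T2, N2, pu[1], U3), (U3, T3, N3, pu[2], VI))
        ):
            P[u, D] = q
            P[u, t] = live * p_ref * adh
            P[u, n] = live * p_ref * (1.0 - adh)
            stay = live * (1.0 - p_ref)
            P[u, nxt] = stay * prog
            P[u, u] = stay * (1.0 - prog)
        for t, prog, nxt in ((T1, pt[0], T2), (T2, pt[1], T3), (T3, pt[2], VI)):
            P[t, D] = q
            P[t, nxt] = live * prog
            P[t, t] = live * (1.0 - prog)
        for n, prog, nxt in ((N1, pu[0], N2), (N2, pu[1], N3), (N3, pu[2], VI)):
            P[n, D] = q
            P[n, nxt] = live * prog
            P[n, n] = live * (1.0 - prog)
        P[VI, D] = q
        P[VI, VI] = live
        P[D, D] = 1.0
        return P

    costs = np.zeros(12)
    costs[T1] = pm["glaucoma.cost.mild_annual"]
    costs[T2] = pm["glaucoma.cost.moderate_annual"]
    costs[T3] = pm["glaucoma.cost.severe_annual"]
    costs[VI] = pm["glaucoma.cost.vi_annual"]
    utils = np.zeros(12)
    utils[W] = pm["utility.well_baseline"]
    utils[[U1, T1, N1]] = pm["utility.glaucoma_mild"]
    utils[[U2, T2, N2]] = pm["utility.glaucoma_moderate"]
    utils[[U3, T3, N3]] = pm["utility.glaucoma_severe"]
    utils[VI] = pm["utility.visual_impairment"]
    tc = np.zeros((12, 12))
    c_ref = pm["eye.cost.optometrist_test"] + pm["eye.cost.diagnosis_test"]
    for u, t, n in ((U1, T1, N1), (U2, T2, N2), (U3, T3, N3)):
        tc[u, t] = tc[u, n] = c_ref
    init = np.zeros(12)
    init[W] = 1.0
    return MarkovModel(
        GLA_STATES, matrix, _const(costs), _const(utils),
        start_age=ctx.base_age, initial_occupancy=init,
        transition_costs=lambda age: tc,
    )


REQUIRED_GLA = (
    "glaucoma.incidence.40_49", "glaucoma.incidence.50_64", "glaucoma.incidence.65_plus",
    "eye.p_referred.ahc", "eye.p_referred.standard", "glaucoma.adherence",
    "glaucoma.p_progress.mild_to_moderate.treated", "glaucoma.p_progress.mild_to_moderate.untreated",
    "glaucoma.p_progress.moderate_to_severe.treated", "glaucoma.p_progress.moderate_to_severe.untreated",
    "glaucoma.p_progress.severe_to_vi.treated", "glaucoma.p_progress.severe_to_vi.untreated",
    "eye.cost.optometrist_test", "eye.cost.diagnosis_test",
    "glaucoma.cost.mild_annual", "glaucoma.cost.moderate_annual", "glaucoma.cost.severe_annual",
    "glaucoma.cost.vi_annual",
    "utility.well_baseline", "utility.glaucoma_mild", "utility.glaucoma_moderate",
    "utility.glaucoma_severe", "utility.visual_impairment",
)


# ---------------------------------------------------------------------------
# osteoporosis (start age 50)

OST_STATES = (
    "Well", "OP-Undetected", "OP-Treated", "OP-Untreated",
    "HipFx-Y1", "HipFx-Y2", "Post-Fx", "Dead",
)


def osteoporosis(arm: Arm, pm: Mapping[str, float], ctx: ModelContext) -> MarkovModel:
    """Osteoporosis screening: investigation (DXA) with an arm-specific
    probability, near-universal prescription, medication that lowers the
    hip-fracture risk, and a two-year fracture cost tunnel."""
    W, U, T, N, F1, F2, PF, D = range(8)
    p_inv = pm[f"osteoporosis.p_investigated.{arm}"]
    p_rx = pm["osteoporosis.p_prescribed"]
    rr_tx = pm["osteoporosis.rr_fracture_treated"]

    def matrix(age: int, _pm) -> np.ndarray:
        q = ctx.qx_at(age)
        inc = banded(pm, "osteoporosis.incidence", age)
        f = banded(pm, "osteoporosis.p_fracture", age)
        live = 1.0 - q
        P = np.zeros((8, 8))
        P[W, D] = q
        P[W, U] = live * inc
        P[W, W] = live * (1.0 - inc)
        P[U, D] = q
        P[U, F1] = live * f
        rest = live * (1.0 - f)
        P[U, T] = rest * p_inv * p_rx
        P[U, N] = rest * p_inv * (1.0 - p_rx)
        P[U, U] = rest * (1.0 - p_inv)
        P[T, D] = q
        P[T, F1] = live * f * rr_tx
        P[T, T] = live * (1.0 - f * rr_tx)
        P[N, D] = q
        P[N, F1] = live * f
        P[N, N] = live * (1.0 - f)
        P[F1, D] = q
        P[F1, F2] = live
        P[F2, D] = q
        P[F2, PF] = live
        P[PF, D] = q
        P[PF, PF] = live
        P[D, D] = 1.0
        return P

    base_costs = np.zeros(8)
    base_costs[T] = pm["osteoporosis.cost.medication_annual"]
    base_costs[F1] = pm["osteoporosis.cost.fracture_year1"]
    base_costs[F2] = pm["osteoporosis.cost.fracture_year2"]

    u_fx1 = pm["utility.hip_fracture_year1"]
    u_5060 = pm["utility.no_fracture.50_60"]
    u_60p = pm["utility.no_fracture.60_plus"]

    def utilities(age: int) -> np.ndarray:
        u_well = u_5060 if age < 60 else u_60p
        u = np.full(8, u_well)
        u[F1] = u_fx1
        u[D] = 0.0
        return u

    tc = np.zeros((8, 8))
    tc[U, T] = tc[U, N] = pm["osteoporosis.cost.dxa"]
    init = np.zeros(8)
    init[W] = 1.0
    return MarkovModel(
        OST_STATES, matrix, _const(base_costs), utilities,
        start_age=50, initial_occupancy=init,
        transition_costs=lambda age: tc,
    )


REQUIRED_OST = (
    "osteoporosis.incidence.50_64", "osteoporosis.incidence.65_plus",
    "osteoporosis.p_fracture.50_64", "osteoporosis.p_fracture.65_plus",
    "osteoporosis.p_investigated.ahc", "osteoporosis.p_investigated.standard",
    "osteoporosis.p_prescribed", "osteoporosis.rr_fracture_treated",
    "osteoporosis.cost.dxa", "osteoporosis.cost.medication_annual",
    "osteoporosis.cost.fracture_year1", "osteoporosis.cost.fracture_year2",
    "utility.hip_fracture_year1", "utility.no_fracture.50_60", "utility.no_fracture.60_plus",
)


# ---------------------------------------------------------------------------
# bowel cancer screening (start age 60)

BOW_STATES = ("Well", "Bowel-Cancer", "Dead")


def bowel_screening(arm: Arm, pm: Mapping[str, float], ctx: ModelContext) -> MarkovModel:
    """Annual FOBT screening. Participation differs between arms by the
    published percentage-point uplift; participants carry the published
    absolute reduction in annual death probability. Screening-cascade costs
    (kits, colonoscopy, polyp removal, bleeding admissions, screen-detected
    treatment) accrue on the cancer-free state; incident cancers in
    non-participants incur the clinically-detected treatment cost."""
    W, C, D = range(3)
    p_std = pm["bowel.participation.standard"]
    p = p_std if arm == "standard" else min(1.0, p_std + pm["bowel.participation_delta_ahc"])
    arr = pm["bowel.arr_death_participants"]

    def matrix(age: int, _pm) -> np.ndarray:
        q_w = min(1.0, max(0.0, ctx.qx_at(age) - p * arr))
        q = ctx.qx_at(age)
        inc = banded(pm, "bowel.incidence", age)
        P = np.zeros((3, 3))
        P[W, D] = q_w
        P[W, C] = (1.0 - q_w) * inc
        P[W, W] = (1.0 - q_w) * (1.0 - inc)
        P[C, D] = q
        P[C, C] = 1.0 - q
        P[D, D] = 1.0
        return P

    screen_cost = p * (
        pm["bowel.cost.fobt"]
        + pm["bowel.p_positive"]
        * pm["bowel.p_clinic_attend"]
        * (
            pm["bowel.cost.colonoscopy"]
            + pm["bowel.p_polyp_given_positive"] * pm["bowel.cost.polyp_removal"]
            + pm["bowel.p_cancer_given_positive"] * pm["bowel.cost.treatment_screen_detected"]
            + pm["bowel.p_bleed_given_investigation"] * pm["bowel.cost.bleed_admission"]
        )
    )
    costs = np.array([screen_cost, 0.0, 0.0])
    utils = np.array([pm["utility.well_baseline"], pm["utility.bowel_cancer"], 0.0])
    tc = np.zeros((3, 3))
    tc[W, C] = (1.0 - p) * pm["bowel.cost.treatment_clinical"]
    init = np.array([1.0, 0.0, 0.0])
    return MarkovModel(
        BOW_STATES, matrix, _const(costs), _const(utils),
        start_age=60, initial_occupancy=init,
        transition_costs=lambda age: tc,
    )


REQUIRED_BOW = (
    "bowel.incidence.50_64", "bowel.incidence.65_plus",
    "bowel.participation.standard", "bowel.participation_delta_ahc",
    "bowel.p_positive", "bowel.p_clinic_attend", "bowel.p_cancer_given_positive",
    "bowel.p_polyp_given_positive", "bowel.p_bleed_given_investigation",
    "bowel.arr_death_participants",
    "bowel.cost.fobt", "bowel.cost.colonoscopy", "bowel.cost.polyp_removal",
    "bowel.cost.bleed_admission", "bowel.cost.treatment_screen_detected",
    "bowel.cost.treatment_clinical",
    "utility.well_baseline", "utility.bowel_cancer",
)


# ---------------------------------------------------------------------------
# breast cancer screening (start age 50, women only)

BRE_STATES = ("Well", "Breast-Cancer", "Dead")


def breast_screening(arm: Arm, pm: Mapping[str, float], ctx: ModelContext) -> MarkovModel:
    """Mammography screening for women. Participants' incident cancers are
    detected early with the published mammogram sensitivity and receive the
    (negative) early-vs-late lifetime treatment-cost delta; invited
    participants carry the relative risk of breast-cancer death and the
    over-diagnosis excess with its treatment cost. The condition result is
    scaled by the female proportion of the cohort."""
    W, C, D = range(3)
    p = pm[f"breast.participation.{arm}"]
    p_det = pm["breast.p_detected_mammogram"]
    rr_death = pm["breast.rr_death_invited"]
    p_ca_death = pm["breast.p_death_cancer_annual"]

    def matrix(age: int, _pm) -> np.ndarray:
        q = ctx.qx_at(age)
        inc = banded(pm, "breast.incidence", age)
        q_c = min(1.0, q + p_ca_death * (p * rr_death + (1.0 - p)))
        P = np.zeros((3, 3))
        P[W, D] = q
        P[W, C] = (1.0 - q) * inc
        P[W, W] = (1.0 - q) * (1.0 - inc)
        P[C, D] = q_c
        P[C, C] = 1.0 - q_c
        P[D, D] = 1.0
        return P

    c_od = pm["breast.cost.overdiagnosis"]
    rr_od = pm["breast.rr_overdiagnosis"]
    c_mam = pm["breast.cost.mammogram"]

    def costs(age: int) -> np.ndarray:
        inc = banded(pm, "breast.incidence", age)
        return np.array([p * c_mam + inc * (rr_od - 1.0) * p * c_od, 0.0, 0.0])

    utils = np.array([pm["utility.well_baseline"], pm["utility.breast_cancer"], 0.0])

    def trans_costs(age: int) -> np.ndarray:
        delta = (
            pm["breast.cost.delta_early_late_under65"]
            if age < 65
            else pm["breast.cost.delta_early_late_65_plus"]
        )
        tc = np.zeros((3, 3))
        tc[W, C] = p * p_det * delta
        return tc

    init = np.array([1.0, 0.0, 0.0])
    return MarkovModel(
        BRE_STATES, matrix, costs, _const(utils),
        start_age=50, initial_occupancy=init,
        transition_costs=trans_costs,
    )


REQUIRED_BRE = (
    "breast.incidence.50_64", "breast.incidence.65_plus",
    "breast.participation.ahc", "breast.participation.standard",
    "breast.p_detected_mammogram", "breast.rr_death_invited", "breast.rr_overdiagnosis",
    "breast.cost.mammogram", "breast.cost.overdiagnosis",
    "breast.cost.delta_early_late_under65", "breast.cost.delta_early_late_65_plus",
    "breast.female_proportion", "breast.p_death_cancer_annual",
    "utility.well_baseline", "utility.breast_cancer",
)


BUILDERS = {
    "hypertension": hypertension,
    "glaucoma": glaucoma,
    "osteoporosis": osteoporosis,
    "bowel_screening": bowel_screening,
    "breast_screening": breast_screening,
}

REQUIRED = {
    "hypertension": REQUIRED_HT,
    "glaucoma": REQUIRED_GLA,
    "osteoporosis": REQUIRED_OST,
    "bowel_screening": REQUIRED_BOW,
    "breast_screening": REQUIRED_BRE,
}
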