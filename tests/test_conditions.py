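import numpy as np
import pytest

from ahc_cua.conditions import (
    ALL_CONDITIONS,
    ConditionError,
    build_state_model,
    evaluate_cascade_condition,
    incremental_condition,
    required_parameters,
)
from ahc_cua.conditions.state_models import GLA_STATES, HT_STATES
from ahc_cua.mortality import read_life_table
from ahc_cua.synthetic import null_effect_parameter_set
import ahc_cua.conditions as cond_mod


def test_null_effect_forces_zero_increment_everywhere(fixture_pset, ctx):
    """Equalising every arm-differentiating parameter must zero every
    condition's incremental cost and QALYs exactly (arm symmetry)."""
    pm = null_effect_parameter_set(fixture_pset).base_points()
    for condition in ALL_CONDITIONS:
        res = incremental_condition(condition, pm, ctx)
        assert res.inc_cost == pytest.approx(0.0, abs=1e-9), condition
        assert res.inc_qaly == pytest.approx(0.0, abs=1e-9), condition


def test_hypertension_null_incidence_never_leaves_well(fixture_pset, ctx):
    pset = fixture_pset
    for band in ("40_49", "50_64", "65_plus"):
        pset = pset.pin(f"hypertension.incidence.{band}", 0.0)
    pm = pset.base_points()
    res = incremental_condition("hypertension", pm, ctx)
    assert res.pv_cost["ahc"] == 0.0 and res.pv_cost["standard"] == 0.0


def test_hypertension_managed_death_is_unmanaged_times_rr(base_pm, ctx):
    model = build_state_model("hypertension", "ahc", base_pm, ctx)
    age = 55
    P = model.transition_rule(age, base_pm)
    M = HT_STATES.index("HT-Managed")
    D = HT_STATES.index("Dead")
    q = ctx.qx_at(age)
    assert P[M, D] == pytest.approx(q * 0.86)  # 40-59 band midpoint RR


def test_glaucoma_progression_rates_treated_vs_untreated(base_pm, ctx):
    model = build_state_model("glaucoma", "standard", base_pm, ctx)
    age = 60
    P = model.transition_rule(age, base_pm)
    live = 1.0 - ctx.qx_at(age)
    T3, N3, VI = (GLA_STATES.index(s) for s in
                  ("Treated-Severe", "Untreated-Severe", "Visual-Impairment"))
    assert P[T3, VI] == pytest.approx(live * 0.06)
    assert P[N3, VI] == pytest.approx(live * 0.10)


def test_bowel_participants_death_reduction_before_survival_weighting(base_pm, ctx):
    ahc = build_state_model("bowel_screening", "ahc", base_pm, ctx)
    std = build_state_model("bowel_screening", "standard", base_pm, ctx)
    age = 65
    d_ahc = ahc.transition_rule(age, base_pm)[0, 2]
    d_std = std.transition_rule(age, base_pm)[0, 2]
    delta_participation = base_pm["bowel.participation_delta_ahc"]
    assert d_std - d_ahc == pytest.approx(delta_participation * 0.0101)


def test_diabetes_obesity_stratum_weights(fixture_pset, ctx):
    """With unit QALY delta in one stratum and zero in the other, the
    incremental QALYs split 33.5 / 66.5."""
    ow = fixture_pset.pin("diabetes.qaly.delta_managed_overweight", 1.0)
    ow = ow.pin("diabetes.qaly.delta_managed_non_overweight", 0.0)
    now = fixture_pset.pin("diabetes.qaly.delta_managed_overweight", 0.0)
    now = now.pin("diabetes.qaly.delta_managed_non_overweight", 1.0)
    q_ow = evaluate_cascade_condition("diabetes", ow.base_points(), ctx).inc_qaly
    q_now = evaluate_cascade_condition("diabetes", now.base_points(), ctx).inc_qaly
    assert q_ow / q_now == pytest.approx(0.335 / 0.665)


def test_hearing_one_cycle_benefit_matches_branch_enumeration(fixture_pset):
    """One-cycle toy with survival one: the aided probability must equal the
    exhaustive product over the branch tree, referral x (1-wax) x attend x
    need x accept."""
    lt = read_life_table("40,0.0\n41,1.0\n")
    ctx1 = cond_mod.ModelContext(life_table=lt, discount_rate=0.0, base_age=40, age_cap=41)
    pset = fixture_pset
    for name in ("hearing.utility.gain_wax", "hearing.cost.wax_removal",
                 "hearing.cost.specialist_assessment", "hearing.cost.aid_assessment",
                 "hearing.cost.aid_initial", "hearing.cost.aid_followon_annual"):
        pset = pset.pin(name, 0.0)
    pset = pset.pin("hearing.utility.gain_aid", 1.0)
    pm = pset.base_points()
    res = evaluate_cascade_condition("hearing", pm, ctx1)
    for arm in ("ahc", "standard"):
        expected_aided = (
            pm["hearing.p_problem_annual"]
            * pm[f"hearing.p_referred.{arm}"]
            * (1.0 - pm["hearing.p_wax"])
            * pm["hearing.p_attend_specialist"]
            * pm["hearing.p_aid_required"]
            * pm["hearing.p_aid_accepted"]
        )
        # one cycle, trapezoid on (0, aided): accrued QALYs = aided / 2
        assert res.pv_qaly[arm] == pytest.approx(expected_aided / 2)


@pytest.mark.parametrize("condition, ahc_param", [
    ("glaucoma", "eye.p_referred.ahc"),
    ("cataract", "eye.p_referred.ahc"),
    ("hearing", "hearing.p_referred.ahc"),
])
def test_raising_ahc_referral_never_lowers_qaly_gain(fixture_pset, ctx, condition, ahc_param):
    lowered = fixture_pset.pin(ahc_param, 0.7).base_points()
    raised = fixture_pset.pin(ahc_param, 0.95).base_points()
    q_low = incremental_condition(condition, lowered, ctx).inc_qaly
    q_high = incremental_condition(condition, raised, ctx).inc_qaly
    assert q_high >= q_low - 1e-12


def test_conditions_are_isolated_from_each_other(fixture_pset, ctx):
    """Perturbing one condition's parameters must not move any other
    condition's result."""
    base = fixture_pset.base_points()
    perturbed = fixture_pset.pin("bowel.cost.colonoscopy", 9999.0).base_points()
    for condition in ALL_CONDITIONS:
        if condition == "bowel_screening":
            continue
        a = incremental_condition(condition, base, ctx)
        b = incremental_condition(condition, perturbed, ctx)
        assert a.inc_cost == b.inc_cost and a.inc_qaly == b.inc_qaly, condition


def test_cascade_branch_probabilities_stay_in_unit_interval(fixture_pset):
    rng = np.random.default_rng(99)
    from ahc_cua.parameters import sample_parameters

    branch_names = [
        n for n in fixture_pset.names()
        if fixture_pset[n].category in ("probability", "proportion")
    ]
    for _ in range(50):
        pm = sample_parameters(fixture_pset, rng)
        for n in branch_names:
            assert 0.0 <= pm[n] <= 1.0, n
            assert 0.0 <= 1.0 - pm[n] <= 1.0, n


def test_incremental_equals_per_arm_difference_to_machine_precision(base_pm, ctx):
    for condition in ALL_CONDITIONS:
        r = incremental_condition(condition, base_pm, ctx)
        assert r.inc_cost == r.pv_cost["ahc"] - r.pv_cost["standard"]
        assert r.inc_qaly == r.pv_qaly["ahc"] - r.pv_qaly["standard"]


def test_unknown_condition_and_missing_parameters_error(base_pm, ctx):
    with pytest.raises(ConditionError, match="unknown"):
        incremental_condition("dementia", base_pm, ctx)
    with pytest.raises(ConditionError, match="unknown"):
        build_state_model("diabetes", "ahc", base_pm, ctx)  # cascade, not state model
    with pytest.raises(KeyError):
        build_state_model("hypertension", "ahc", {}, ctx)


def test_required_parameter_lists_cover_every_lookup(fixture_pset, ctx):
    """Evaluating a condition with only its declared parameters present must
    succeed -- the declared dependency list is complete."""
    base = fixture_pset.base_points()
    for condition in ALL_CONDITIONS:
        needed = set(required_parameters(condition))
        if condition == "breast_screening":
            needed.add("breast.female_proportion")
        pm = {k: base[k] for k in needed}
        incremental_condition(condition, pm, ctx)
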