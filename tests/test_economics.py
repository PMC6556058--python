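import math

import numpy as np
import pytest

from ahc_cua.conditions import ConditionResult
from ahc_cua.economics import (
    EconomicsError,
    aggregate_strategy,
    annuity_factor,
    ceac,
    icer,
    intervention_components,
    intervention_cost_pv,
    intervention_yearly_cost,
    nmb,
)
from ahc_cua.mortality import adjust_id_mortality, survival_curve
from ahc_cua.synthetic import gompertz_life_table


class TestInterventionCosting:
    def test_gp_twenty_minutes_at_216_per_hour(self):
        assert intervention_yearly_cost([("gp", 20, 216)]) == 72

    def test_support_worker_eight_hours(self):
        assert intervention_yearly_cost([("support", 480, 17)]) == 136

    def test_social_worker_rounds_to_seven(self):
        assert intervention_yearly_cost([("social", 5, 79)]) == 7  # 6.58 -> 7

    def test_all_components_total_258(self, base_pm):
        components = intervention_components(base_pm)
        assert intervention_yearly_cost(components) == 258
        assert base_pm["intervention.yearly_cost"] == 258

    def test_negative_quantity_rejected(self):
        with pytest.raises(EconomicsError):
            intervention_yearly_cost([("gp", -1, 216)])


class TestInterventionPV:
    def test_full_survival_two_cycles(self):
        pv = intervention_cost_pv(258.0, [1.0, 1.0, 1.0], 0.035)
        assert pv == pytest.approx(258 + 258 / 1.035)

    def test_zero_cost_is_zero(self):
        assert intervention_cost_pv(0.0, [1.0, 0.9, 0.8], 0.035) == 0.0

    def test_gompertz_annuity_matches_independent_summation(self):
        table = adjust_id_mortality(gompertz_life_table(), 3.0)
        S = survival_curve(table, 40, 100).values
        rate = 0.035
        oracle = math.fsum(
            0.5 * (S[k] + S[k + 1]) / (1 + rate) ** k for k in range(len(S) - 1)
        )
        assert annuity_factor(S, rate) == pytest.approx(oracle, rel=1e-12)


class TestAggregation:
    def _cond(self, tag, c, q):
        return ConditionResult(tag, {"ahc": c, "standard": 0.0}, {"ahc": q, "standard": 0.0})

    def test_empty_condition_list(self):
        s = aggregate_strategy([], 100.0)
        assert s.inc_cost_total == 100.0 and s.inc_qaly_total == 0.0

    def test_sums_and_order_independence(self):
        a, b = self._cond("a", 10.0, 0.03), self._cond("b", -5.0, 0.04)
        s1 = aggregate_strategy([a, b], 50.0)
        s2 = aggregate_strategy([b, a], 50.0)
        assert s1.inc_qaly_total == pytest.approx(0.07)
        assert s1.inc_cost_total == pytest.approx(55.0)
        assert s1 == s2

    def test_duplicate_tags_rejected(self):
        with pytest.raises(EconomicsError, match="duplicate"):
            aggregate_strategy([self._cond("a", 1, 0), self._cond("a", 2, 0)], 0.0)


class TestIcer:
    def test_plain_ratio(self):
        assert icer(100.0, 0.01).value == pytest.approx(10_000.0)
        assert icer(100.0, 0.01).flag == ""

    def test_dominated_flag(self):
        r = icer(100.0, 0.0)
        assert math.isnan(r.value) and r.flag == "dominated"

    def test_dominant_flag_keeps_negative_ratio(self):
        r = icer(-50.0, 0.01)
        assert r.value == pytest.approx(-5_000.0) and r.flag == "dominant"

    def test_undefined_when_both_zero(self):
        assert icer(0.0, 0.0).flag == "undefined"


class TestNmbCeac:
    def test_nmb_example(self):
        assert nmb(1000.0, 0.1, 20_000.0) == pytest.approx(1000.0)

    def test_all_identical_positive_draws_give_probability_one(self):
        draws = [(1000.0, 0.1)] * 10
        assert ceac(draws, [20_000.0]) == [(20_000.0, 1.0)]

    def test_probability_equals_exhaustive_count(self):
        rng = np.random.default_rng(3)
        draws = np.column_stack([rng.normal(1000, 500, 1000), rng.normal(0.05, 0.03, 1000)])
        t = 20_000.0
        expected = sum(1 for c, q in draws if t * q - c > 0) / len(draws)
        assert ceac(draws, [t])[0][1] == pytest.approx(expected)

    def test_ceac_nondecreasing_when_all_qalys_positive(self):
        rng = np.random.default_rng(4)
        draws = np.column_stack([rng.normal(1000, 500, 500), rng.uniform(0.01, 0.1, 500)])
        ts = [0, 5_000, 10_000, 20_000, 50_000, 100_000]
        probs = [p for _, p in ceac(draws, ts)]
        assert all(b >= a for a, b in zip(probs, probs[1:]))

    def test_empty_draws_rejected(self):
        with pytest.raises(EconomicsError, match="empty"):
            ceac(np.empty((0, 2)), [20_000.0])
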