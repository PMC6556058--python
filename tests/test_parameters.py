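import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ahc_cua.parameters import (
    ParameterError,
    ParamSpec,
    base_point,
    build_distribution,
    load_parameter_set,
    resolve_point,
    sample_parameters,
)

MINI_CONFIG = """
metadata: {price_year: 2016, discount_rate: 0.035, cycle_length_years: 1}
parameters:
- {name: hypertension.incidence.40_49, category: probability, low: 0.35, high: 1.14, unit: percent}
- {name: zero.range, category: probability, low: 0, high: 0}
"""


def test_percent_ranges_normalised_to_proportions():
    pset = load_parameter_set(MINI_CONFIG)
    spec = pset["hypertension.incidence.40_49"]
    assert spec.low == pytest.approx(0.0035)
    assert spec.high == pytest.approx(0.0114)


def test_degenerate_zero_range_is_valid_point():
    pset = load_parameter_set(MINI_CONFIG)
    assert base_point(pset["zero.range"]) == 0.0


def test_range_inversion_rejected():
    with pytest.raises(ParameterError, match="range inversion"):
        ParamSpec(name="bad.cost", category="cost", low=19, high=16)


def test_probability_outside_unit_interval_rejected():
    with pytest.raises(ParameterError):
        ParamSpec(name="bad.p", category="probability", low=0.0, high=1.5)


def test_duplicate_names_rejected():
    cfg = MINI_CONFIG + "- {name: zero.range, category: probability, low: 0, high: 0}\n"
    with pytest.raises(ParameterError, match="duplicate"):
        load_parameter_set(cfg)


@pytest.mark.parametrize(
    "low, high, rule, expected",
    [
        (0.0035, 0.0114, "midpoint", 0.00745),
        (258.0, 258.0, "midpoint", 258.0),
        (258.0, 258.0, "low", 258.0),
        (-14347.0, -11739.0, "midpoint", -13043.0),
    ],
)
def test_resolve_point_rules(low, high, rule, expected):
    spec = ParamSpec(name="x", category="cost", low=low, high=high)
    assert resolve_point(spec, rule) == pytest.approx(expected)


def test_point_override_requires_a_point():
    spec = ParamSpec(name="x", category="cost", low=1.0, high=2.0)
    with pytest.raises(ParameterError, match="point_override"):
        resolve_point(spec, "point_override")
    with_point = ParamSpec(name="x", category="cost", low=1.0, high=2.0, point=1.7)
    assert resolve_point(with_point, "point_override") == 1.7


@given(
    low=st.floats(-1e6, 1e6, allow_nan=False),
    width=st.floats(0, 1e6, allow_nan=False),
)
@settings(max_examples=200, deadline=None)
def test_midpoint_is_the_mean_of_the_bounds(low, width):
    spec = ParamSpec(name="x", category="cost", low=low, high=low + width)
    assert resolve_point(spec, "midpoint") == pytest.approx((low + (low + width)) / 2)


class TestDistributions:
    def test_beta_ci95_quantiles_bracket_the_range(self):
        spec = ParamSpec(name="p", category="probability", low=0.2, high=0.4)
        d = build_distribution(spec, "ci95")
        assert d.family == "beta"
        assert d.mean() == pytest.approx(0.30, abs=1e-9)
        assert d.ppf(0.025) == pytest.approx(0.2, abs=0.02)
        assert d.ppf(0.975) == pytest.approx(0.4, abs=0.02)

    def test_gamma_for_nonnegative_cost(self):
        spec = ParamSpec(name="c", category="cost", low=16, high=19)
        d = build_distribution(spec, "ci95")
        assert d.family == "gamma"
        assert d.mean() == pytest.approx(17.5)
        assert d.sample(np.random.default_rng(0), size=1000).min() > 0

    def test_degenerate_range_is_point_mass(self):
        spec = ParamSpec(name="p", category="probability", low=0.5, high=0.5)
        d = build_distribution(spec)
        assert d.family == "point_mass"
        assert d.sample(np.random.default_rng(0)) == 0.5

    def test_positive_delta_never_samples_negative(self):
        spec = ParamSpec(name="g", category="qaly_delta", low=0.084, high=0.963)
        d = build_distribution(spec, "half_range_sd")
        x = d.sample(np.random.default_rng(0), size=20_000)
        assert x.min() >= 0.0
        assert np.mean(x) == pytest.approx(base_point(spec), abs=0.01)

    def test_beta_sample_mean_matches_fitted_mean(self):
        spec = ParamSpec(name="p", category="probability", low=0.2, high=0.4)
        d = build_distribution(spec, "ci95")
        x = d.sample(np.random.default_rng(42), size=10_000)
        assert float(np.mean(x)) == pytest.approx(0.30, abs=0.01)

    def test_every_fixture_distribution_mean_matches_base_point(self, fixture_pset):
        for name, dist in fixture_pset.distributions().items():
            target = base_point(fixture_pset[name])
            scale = max(1.0, abs(target))
            assert dist.mean() == pytest.approx(target, abs=2e-3 * scale), name

    def test_probability_samples_stay_in_unit_interval(self, fixture_pset):
        rng = np.random.default_rng(7)
        for name, dist in fixture_pset.distributions().items():
            if fixture_pset[name].category in ("probability", "proportion", "utility"):
                x = np.atleast_1d(dist.sample(rng, size=10_000))
                assert x.min() >= 0.0 and x.max() <= 1.0, name


def test_sampling_is_deterministic_given_seed(fixture_pset):
    a = sample_parameters(fixture_pset, np.random.default_rng(11))
    b = sample_parameters(fixture_pset, np.random.default_rng(11))
    assert a == b


def test_point_mass_draws_equal_base_case(fixture_pset):
    pinned = fixture_pset
    for name in fixture_pset.names():
        spec = fixture_pset[name]
        pinned = pinned.pin(name, base_point(spec))
    draw = sample_parameters(pinned, np.random.default_rng(0))
    assert draw == pytest.approx(fixture_pset.base_points())


def test_serialisation_round_trip_preserves_resolved_points(fixture_pset):
    reloaded = load_parameter_set(fixture_pset.to_yaml())
    assert reloaded.base_points() == pytest.approx(fixture_pset.base_points())
    assert reloaded.to_yaml() == load_parameter_set(reloaded.to_yaml()).to_yaml()
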