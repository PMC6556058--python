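"""Synthetic inputs: life tables, the packaged parameter fixture, and
randomised parameter scenarios for property tests.

Nothing here downloads anything. The default life table is a Gompertz law
calibrated so that period life expectancy at birth is about 81 years
(England-like) before the intellectual-disability mortality adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np

from .mortality import LifeTable
from .parameters import ParameterSet, ParamSpec, load_parameter_set

#: Gompertz annual hazard mu(age) = a * exp(b * age); a solved so that life
#: expectancy at birth is 81.0 years at b = 0.095.
DEFAULT_GOMPERTZ_A = 2.5360e-05
DEFAULT_GOMPERTZ_B = 0.095
DEFAULT_MAX_AGE = 100


@dataclass(frozen=True)
class GompertzSpec:
    a: float = DEFAULT_GOMPERTZ_A
    b: float = DEFAULT_GOMPERTZ_B
    max_age: int = DEFAULT_MAX_AGE

    def __post_init__(self):
        if self.a <= 0 or self.b < 0:
            raise ValueError("require a > 0 and b >= 0")


def gompertz_life_table(spec: GompertzSpec = GompertzSpec()) -> LifeTable:
    """qx(age) = 1 - exp(-a e^{b age}), with qx = 1 at the terminal age."""
    ages = np.arange(0, spec.max_age + 1)
    qx = 1.0 - np.exp(-spec.a * np.exp(spec.b * ages))
    qx[-1] = 1.0
    return LifeTable(ages, qx)


def paper_parameter_fixture() -> ParameterSet:
    """The packaged fixture encoding every published model input."""
    text = resources.files("ahc_cua").joinpath("data/parameters.yaml").read_text()
    return load_parameter_set(text)


def assumption_entries(pset: ParameterSet) -> list[str]:
    """Names of the loudly-tagged non-published placeholders."""
    return sorted(s.name for s in pset if s.provenance == "assumption")


def null_effect_parameter_set(pset: ParameterSet) -> ParameterSet:
    """Equalise every arm-differentiating parameter across strategies.

    With this set the two arms are identical draw-for-draw, so every
    condition's incremental cost and QALY must vanish exactly.
    """
    from .conditions import ARM_EFFECT_PAIRS, ARM_EFFECT_DELTAS  # cycle guard

    out = pset
    for ahc_name, std_name in ARM_EFFECT_PAIRS:
        std = out[std_name]
        out = out.override(ahc_name, low=std.low, high=std.high, point=std.point, sd=std.sd)
    for delta_name in ARM_EFFECT_DELTAS:
        out = out.pin(delta_name, 0.0)
    return out


def random_scenario(seed: int) -> ParameterSet:
    """Structurally valid random variant of the fixture for property tests.

    Probabilities stay in [0,1], costs stay non-negative, relative risks stay
    positive; ranges are jittered around the fixture's so degenerate and
    extreme corners appear across seeds. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    base = paper_parameter_fixture()
    entries = []
    for s in base:
        width = s.high - s.low
        mid = 0.5 * (s.low + s.high)
        if width == 0.0 or s.category == "resource_quantity":
            entries.append(s)
            continue
        shift = rng.normal(0.0, 0.25) * max(width, abs(mid) * 0.1)
        scale = rng.uniform(0.0, 1.5)  # 0 produces degenerate point ranges
        lo = mid + shift - 0.5 * scale * width
        hi = mid + shift + 0.5 * scale * width
        if s.category in ("probability", "proportion"):
            lo, hi = float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
        elif s.category == "utility":
            lo, hi = float(np.clip(lo, 0, 1)), float(np.clip(hi, 0, 1))
        elif s.category == "relative_risk":
            lo, hi = max(lo, 1e-3), max(hi, 1e-3)
        elif s.category == "cost" and s.low >= 0:
            lo, hi = max(lo, 0.0), max(hi, 0.0)
        if lo > hi:
            lo, hi = hi, lo
        entries.append(
            ParamSpec(
                name=s.name, condition=s.condition, category=s.category,
                low=lo, high=hi, point=None, sd=None, age_band=s.age_band,
                arm=s.arm, provenance=s.provenance, source_note=s.source_note,
            )
        )
    return ParameterSet(entries, base.metadata)
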