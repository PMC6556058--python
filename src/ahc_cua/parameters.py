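"""Model inputs: named parameters with printed ranges, base-case points and
probabilistic-sensitivity-analysis distributions.

Every quantity the decision model consumes is registered here by name, with the
range it was published with, its category (probability, cost, utility, ...) and
its provenance. Ranges are resolved to base-case points (midpoint unless an
explicit point is recorded) and to sampling distributions following the usual
health-economics conventions: beta for probabilities/proportions/utilities,
gamma for non-negative costs, lognormal for relative risks, truncated normal
for signed differences, a point mass for degenerate ranges.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Optional

import numpy as np
import yaml
from scipy import stats

log = logging.getLogger(__name__)

CATEGORIES = frozenset(
    {
        "probability",
        "probability_difference",
        "cost",
        "utility",
        "utility_delta",
        "qaly_delta",
        "relative_risk",
        "proportion",
        "resource_quantity",
    }
)

#: categories whose values live on [0, 1]
_UNIT_INTERVAL = frozenset({"probability", "proportion"})

POINT_RULES = ("midpoint", "low", "high", "point_override")


class ParameterError(ValueError):
    """Raised for malformed parameter specifications or configs."""


@dataclass(frozen=True)
class ParamSpec:
    """One named model input with its printed range.

    ``low``/``high`` bound the printed range (already unit-normalised, i.e.
    percentages divided by 100). ``point`` records an explicitly printed
    base-case value; ``sd`` a printed standard deviation (mean/SD inputs).
    """

    name: str
    condition: str = "global"
    category: str = "probability"
    low: float = 0.0
    high: float = 0.0
    point: Optional[float] = None
    sd: Optional[float] = None
    age_band: Optional[tuple[int, int]] = None
    arm: Optional[str] = None
    provenance: str = "paper"
    source_note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ParameterError(f"{self.name}: unknown category {self.category!r}")
        if self.low > self.high:
            raise ParameterError(
                f"{self.name}: range inversion (low={self.low} > high={self.high})"
            )
        if self.point is not None and not (self.low <= self.point <= self.high):
            raise ParameterError(
                f"{self.name}: point {self.point} outside [{self.low}, {self.high}]"
            )
        if self.category in _UNIT_INTERVAL and (self.low < 0 or self.high > 1):
            raise ParameterError(
                f"{self.name}: {self.category} outside [0, 1] "
                f"({self.low}, {self.high})"
            )
        if self.category == "utility" and self.high > 1:
            raise ParameterError(f"{self.name}: utility above 1 ({self.high})")
        if self.arm is not None and self.arm not in ("ahc", "standard", "both"):
            raise ParameterError(f"{self.name}: unknown arm {self.arm!r}")


def resolve_point(spec: ParamSpec, rule: str = "midpoint") -> float:
    """Resolve a printed range to a single base-case number.

    ``midpoint`` returns the arithmetic mean of the bounds, ``low``/``high``
    the respective bound, ``point_override`` the explicitly recorded point
    (an error when none was recorded).
    """
    if rule == "midpoint":
        return 0.5 * (spec.low + spec.high)
    if rule == "low":
        return spec.low
    if rule == "high":
        return spec.high
    if rule == "point_override":
        if spec.point is None:
            raise ParameterError(f"{spec.name}: point_override requested but no point")
        return spec.point
    raise ParameterError(f"unknown point rule {rule!r}")


def base_point(spec: ParamSpec) -> float:
    """Default base-case resolution: the printed point when one exists,
    otherwise the range midpoint."""
    if spec.point is not None:
        return spec.point
    return resolve_point(spec, "midpoint")


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class Distribution:
    """A fitted sampling distribution with explicit support."""

    family: str  # beta | gamma | lognormal | truncated_normal | point_mass
    parameters: tuple[float, ...]
    support: tuple[float, float]

    def _frozen(self):
        if self.family == "beta":
            a, b = self.parameters
            return stats.beta(a, b)
        if self.family == "gamma":
            shape, scale = self.parameters
            return stats.gamma(shape, scale=scale)
        if self.family == "lognormal":
            mu, sigma = self.parameters
            return stats.lognorm(sigma, scale=math.exp(mu))
        if self.family == "truncated_normal":
            loc, scale, lo, hi = self.parameters
            return stats.truncnorm((lo - loc) / scale, (hi - loc) / scale, loc=loc, scale=scale)
        raise ParameterError(f"no frozen form for {self.family}")

    def mean(self) -> float:
        if self.family == "point_mass":
            return self.parameters[0]
        if self.family == "scaled_beta":
            a, b, lo, hi = self.parameters
            return lo + (hi - lo) * a / (a + b)
        return float(self._frozen().mean())

    def ppf(self, q: float) -> float:
        if self.family == "point_mass":
            return self.parameters[0]
        if self.family == "scaled_beta":
            a, b, lo, hi = self.parameters
            return lo + (hi - lo) * float(stats.beta(a, b).ppf(q))
        return float(self._frozen().ppf(q))

    def sample(self, rng: np.random.Generator, size=None):
        if self.family == "point_mass":
            v = self.parameters[0]
            return v if size is None else np.full(size, v)
        if self.family == "scaled_beta":
            a, b, lo, hi = self.parameters
            x = lo + (hi - lo) * rng.beta(a, b, size=size)
        else:
            x = self._frozen().rvs(size=size, random_state=rng)
        return np.clip(x, self.support[0], self.support[1])


def _beta_from_moments(m: float, v: float, name: str) -> Distribution:
    vmax = m * (1.0 - m)
    if v >= vmax:
        # moment matching infeasible on [0,1]: shrink the SD to the largest
        # feasible value (logged, per the loading contract)
        log.warning(json.dumps({"event": "sd_shrunk", "name": name, "sd": math.sqrt(v)}))
        v = 0.95 * vmax
    k = vmax / v - 1.0
    return Distribution("beta", (m * k, (1.0 - m) * k), (0.0, 1.0))


def _truncnorm_mean_matched(m: float, sd: float, lo: float, hi: float) -> Distribution:
    """Truncated normal whose *truncated* mean equals ``m`` (the location is
    re-solved when truncation would otherwise bias the mean)."""

    def mean_at(loc: float) -> float:
        a, b = (lo - loc) / sd, (hi - loc) / sd
        return float(stats.truncnorm.mean(a, b, loc=loc, scale=sd))

    loc = m
    if abs(mean_at(loc) - m) > 1e-9 * max(1.0, abs(m)):
        from scipy.optimize import brentq

        span = 8 * sd
        try:
            loc = brentq(lambda x: mean_at(x) - m, m - span, m + span, xtol=1e-12)
        except ValueError:
            pass  # unmatchable (m at a support edge): keep the biased fit
    return Distribution("truncated_normal", (loc, sd, lo, hi), (lo, hi))


#: how a printed (low, high) range maps to a sampling SD. ``half_range_sd``
#: reads the range as mean +/- one SD -- the reading that reproduces the
#: published PSA dispersion (see docs/methods.md) -- and is the default;
#: ``ci95`` reads it as a central 95% interval; ``minmax`` as hard support.
INTERPRETATIONS = ("half_range_sd", "ci95", "minmax")
DEFAULT_INTERPRETATION = "half_range_sd"


def build_distribution(spec: ParamSpec, interpretation: str = DEFAULT_INTERPRETATION) -> Distribution:
    """Fit a PSA distribution to a printed range.

    The fitted mean always equals the base-case point; ``interpretation``
    (see :data:`INTERPRETATIONS`) sets the spread implied by the range.
    """
    if interpretation not in INTERPRETATIONS:
        raise ParameterError(f"unknown range interpretation {interpretation!r}")
    m = base_point(spec)
    degenerate = spec.high == spec.low and not spec.sd
    if degenerate:
        return Distribution("point_mass", (m,), (m, m))

    if spec.sd:
        sd = spec.sd
    elif interpretation == "half_range_sd":
        sd = (spec.high - spec.low) / 2.0
    else:
        sd = (spec.high - spec.low) / (2 * 1.959964)
    v = sd * sd
    cat = spec.category

    if interpretation == "minmax":
        lo, hi = spec.low, spec.high
        mm = (m - lo) / (hi - lo)
        kappa = 4.0  # mild concentration; mean matched exactly
        return Distribution("scaled_beta", (mm * kappa, (1 - mm) * kappa, lo, hi), (lo, hi))

    if cat in ("probability", "proportion", "utility"):
        if m <= 0.0 or m >= 1.0:
            return Distribution("point_mass", (m,), (m, m))
        return _beta_from_moments(m, v, spec.name)
    if cat == "cost" and spec.low >= 0:
        if m <= 0:
            return Distribution("point_mass", (m,), (m, m))
        return Distribution("gamma", (m * m / v, v / m), (0.0, math.inf))
    if cat == "relative_risk":
        if spec.low <= 0:
            lo, hi = m - 4 * sd, m + 4 * sd
            return _truncnorm_mean_matched(m, sd, max(0.0, lo), hi)
        log_div = 2.0 if interpretation == "half_range_sd" else 2 * 1.959964
        sigma = (math.log(spec.high) - math.log(spec.low)) / log_div
        mu = math.log(m) - 0.5 * sigma * sigma
        return Distribution("lognormal", (mu, sigma), (0.0, math.inf))
    # differences (and the signed lifetime-cost deltas): sign-preserving
    # truncation -- a printed range that is entirely positive (negative)
    # documents the direction of effect, so sampling must not cross zero;
    # mixed-sign ranges stay unbounded within +/-4 SD
    lo, hi = m - 4 * sd, m + 4 * sd
    if spec.low >= 0:
        lo = max(lo, 0.0)
    if spec.high <= 0:
        hi = min(hi, 0.0)
    return _truncnorm_mean_matched(m, sd, lo, hi)


# ---------------------------------------------------------------------------
# parameter set


_MANDATORY_METADATA = ("price_year", "discount_rate", "cycle_length_years")


class ParameterSet:
    """Immutable registry of :class:`ParamSpec` plus global metadata."""

    def __init__(self, entries: Iterable[ParamSpec], metadata: Mapping[str, float]):
        table: dict[str, ParamSpec] = {}
        for spec in entries:
            if spec.name in table:
                raise ParameterError(f"duplicate parameter name {spec.name!r}")
            table[spec.name] = spec
        missing = [k for k in _MANDATORY_METADATA if k not in metadata]
        if missing:
            raise ParameterError(f"missing mandatory metadata: {missing}")
        rate = float(metadata["discount_rate"])
        if not (0.0 <= rate < 1.0):
            raise ParameterError(f"discount_rate outside [0,1): {rate}")
        self._entries = table
        self._metadata = dict(metadata)
        self._dist_cache: dict[str, dict[str, Distribution]] = {}

    # mapping-ish surface -------------------------------------------------
    def __getitem__(self, name: str) -> ParamSpec:
        try:
            return self._entries[name]
        except KeyError:
            raise ParameterError(f"unknown parameter {name!r}") from None

    def __contains__(self, name: str) -> bool:
        return name in self._entries

    def __iter__(self):
        return iter(self._entries.values())

    def __len__(self) -> int:
        return len(self._entries)

    def names(self) -> list[str]:
        return list(self._entries)

    @property
    def metadata(self) -> dict:
        return dict(self._metadata)

    @property
    def discount_rate(self) -> float:
        return float(self._metadata["discount_rate"])

    # resolution ----------------------------------------------------------
    def base_points(self, rule: str = "default") -> dict[str, float]:
        """Resolve every entry to its base-case number.

        ``default`` uses the printed point when present and the midpoint
        otherwise; any explicit rule from :data:`POINT_RULES` applies that
        rule uniformly.
        """
        if rule == "default":
            return {n: base_point(s) for n, s in self._entries.items()}
        return {n: resolve_point(s, rule) for n, s in self._entries.items()}

    def distributions(self, interpretation: str = DEFAULT_INTERPRETATION) -> dict[str, Distribution]:
        if interpretation not in self._dist_cache:
            self._dist_cache[interpretation] = {
                n: build_distribution(s, interpretation) for n, s in self._entries.items()
            }
        return self._dist_cache[interpretation]

    def require(self, names: Iterable[str]) -> None:
        """Completeness check: every referenced name resolves; lists all gaps."""
        gaps = sorted(set(names) - set(self._entries))
        if gaps:
            raise ParameterError(f"unresolved parameter names: {gaps}")

    # derivation ----------------------------------------------------------
    def override(self, name: str, *, low=None, high=None, point=None, sd=None) -> "ParameterSet":
        """Return a new set with one entry's numbers replaced."""
        spec = self[name]
        new = replace(
            spec,
            low=spec.low if low is None else low,
            high=spec.high if high is None else high,
            point=point,
            sd=sd,
        )
        entries = dict(self._entries)
        entries[name] = new
        return ParameterSet(entries.values(), self._metadata)

    def pin(self, name: str, value: float) -> "ParameterSet":
        """Collapse one entry to a point mass at ``value`` (one-way SA)."""
        return self.override(name, low=value, high=value, point=value, sd=None)

    # serialisation -------------------------------------------------------
    def to_yaml(self) -> str:
        blocks = []
        for s in self._entries.values():
            d = {"name": s.name, "condition": s.condition, "category": s.category,
                 "low": s.low, "high": s.high}
            if s.point is not None:
                d["point"] = s.point
            if s.sd is not None:
                d["sd"] = s.sd
            if s.age_band is not None:
                d["age_band"] = list(s.age_band)
            if s.arm is not None:
                d["arm"] = s.arm
            if s.provenance != "paper":
                d["provenance"] = s.provenance
            if s.source_note:
                d["source_note"] = s.source_note
            blocks.append(d)
        return yaml.safe_dump(
            {"metadata": self._metadata, "parameters": blocks}, sort_keys=False, width=100
        )


def _norm(value, percent: bool):
    if value is None:
        return None
    return float(value) / 100.0 if percent else float(value)


def load_parameter_set(config_text: str) -> ParameterSet:
    """Parse a YAML parameter config into a validated :class:`ParameterSet`.

    Entries declaring ``unit: percent`` are divided by 100 at load so every
    probability/proportion is stored as a per-cycle proportion.
    """
    try:
        doc = yaml.safe_load(config_text)
    except yaml.YAMLError as exc:  # pragma: no cover - parser detail
        raise ParameterError(f"config does not parse: {exc}") from exc
    if not isinstance(doc, dict) or "parameters" not in doc:
        raise ParameterError("config must be a mapping with a 'parameters' list")
    metadata = doc.get("metadata", {})
    entries = []
    for raw in doc["parameters"]:
        raw = dict(raw)
        percent = raw.pop("unit", None) == "percent"
        band = raw.pop("age_band", None)
        entries.append(
            ParamSpec(
                name=raw["name"],
                condition=raw.get("condition", "global"),
                category=raw.get("category", "probability"),
                low=_norm(raw.get("low", 0.0), percent),
                high=_norm(raw.get("high", 0.0), percent),
                point=_norm(raw.get("point"), percent),
                sd=_norm(raw.get("sd"), percent),
                age_band=tuple(band) if band else None,
                arm=raw.get("arm"),
                provenance=raw.get("provenance", "paper"),
                source_note=raw.get("source_note", ""),
            )
        )
    pset = ParameterSet(entries, metadata)
    log.info(json.dumps({"event": "parameters_loaded", "n": len(pset)}))
    return pset


def sample_parameters(
    parameter_set: ParameterSet,
    rng: np.random.Generator,
    interpretation: str = DEFAULT_INTERPRETATION,
) -> dict[str, float]:
    """One independent draw per parameter, deterministic given the caller's rng."""
    dists = parameter_set.distributions(interpretation)
    return {name: float(dist.sample(rng)) for name, dist in dists.items()}
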