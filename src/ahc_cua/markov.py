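"""Annual-cycle cohort Markov engine.

Deterministic propagation of state-occupancy proportions through per-cycle
transition matrices, with trapezoidal half-cycle correction of state rewards,
one-off rewards attached to transitions, and discounting to a common time
origin. The engine is generic; condition-specific structure lives in
:mod:`ahc_cua.conditions`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

ROW_SUM_TOL = 1e-9


class MarkovError(ValueError):
    pass


@dataclass
class MarkovModel:
    """One condition, one strategy arm.

    ``transition_rule(age, parameter_map)`` returns the square transition
    matrix for the cycle starting at ``age``. Rewards are annual per-state
    accruals, possibly age-dependent; ``transition_costs``/``transition_qalys``
    are optional per-transition one-off rewards (matrices, same shape as the
    transition matrix) applied at the cycle of transition without half-cycle
    correction. Residual probability is never redistributed silently: rows
    must sum to one as built.
    """

    states: tuple[str, ...]
    transition_rule: Callable[[int, Mapping[str, float]], np.ndarray]
    state_costs: Callable[[int], np.ndarray]
    state_utilities: Callable[[int], np.ndarray]
    start_age: int
    initial_occupancy: np.ndarray
    death_states: tuple[str, ...] = ("Dead",)
    transition_costs: Optional[Callable[[int], np.ndarray]] = None
    transition_qalys: Optional[Callable[[int], np.ndarray]] = None

    def __post_init__(self):
        self.initial_occupancy = np.asarray(self.initial_occupancy, dtype=float)
        if abs(self.initial_occupancy.sum() - 1.0) > ROW_SUM_TOL:
            raise MarkovError("initial occupancy must sum to 1")
        missing = set(self.death_states) - set(self.states)
        if missing:
            raise MarkovError(f"death states not in state list: {missing}")

    @property
    def death_index(self) -> np.ndarray:
        return np.array([self.states.index(s) for s in self.death_states])


@dataclass
class CohortTrace:
    """Occupancy by cycle plus per-cycle reward accruals (already
    half-cycle corrected; not yet discounted)."""

    states: tuple[str, ...]
    start_age: int
    occupancy: np.ndarray  # (cycles+1, n_states)
    cost_stream: np.ndarray  # (cycles,)
    qaly_stream: np.ndarray  # (cycles,)

    def to_frame(self) -> pd.DataFrame:
        n = self.occupancy.shape[0]
        df = pd.DataFrame(self.occupancy, columns=list(self.states))
        df.insert(0, "cycle", np.arange(n))
        df.insert(1, "age", self.start_age + np.arange(n))
        df["cost_accrual"] = np.concatenate([self.cost_stream, [np.nan]])
        df["qaly_accrual"] = np.concatenate([self.qaly_stream, [np.nan]])
        return df


def _check_matrix(P: np.ndarray, states, age: int, death_index) -> None:
    bad = np.where(np.abs(P.sum(axis=1) - 1.0) > ROW_SUM_TOL)[0]
    if bad.size:
        i = int(bad[0])
        raise MarkovError(
            f"transition row does not sum to 1 at age {age}, state {states[i]!r} "
            f"(sum={P[i].sum():.12f})"
        )
    if np.any((P < -1e-15) | (P > 1 + 1e-12)):
        i = int(np.argwhere((P < -1e-15) | (P > 1 + 1e-12))[0][0])
        raise MarkovError(f"transition entry outside [0,1] at age {age}, state {states[i]!r}")
    for d in death_index:
        if abs(P[d, d] - 1.0) > ROW_SUM_TOL:
            raise MarkovError(f"death state {states[d]!r} not absorbing at age {age}")


def accrue_rewards(
    occupancy: np.ndarray, cost_reward: np.ndarray, utility_reward: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Trapezoidal half-cycle correction for constant per-state rewards:
    accrual in cycle k is reward . (occ[k]+occ[k+1])/2."""
    occ = np.asarray(occupancy, dtype=float)
    mid = 0.5 * (occ[:-1] + occ[1:])
    return mid @ np.asarray(cost_reward, float), mid @ np.asarray(utility_reward, float)


def run_cohort(
    model: MarkovModel, parameter_map: Mapping[str, float], age_cap: int
) -> CohortTrace:
    """Propagate the cohort from the model's start age to ``age_cap``.

    Per-cycle accruals combine the half-cycle-corrected state rewards with any
    one-off transition rewards (flow through P weighted by start-of-cycle
    occupancy).
    """
    n_cycles = age_cap - model.start_age
    if n_cycles <= 0:
        raise MarkovError("age_cap must exceed start_age")
    S = len(model.states)
    occ = np.empty((n_cycles + 1, S))
    occ[0] = model.initial_occupancy
    cost = np.zeros(n_cycles)
    qaly = np.zeros(n_cycles)
    didx = model.death_index
    for k in range(n_cycles):
        age = model.start_age + k
        P = np.asarray(model.transition_rule(age, parameter_map), dtype=float)
        _check_matrix(P, model.states, age, didx)
        occ[k + 1] = occ[k] @ P
        mid = 0.5 * (occ[k] + occ[k + 1])
        cost[k] = mid @ model.state_costs(age)
        qaly[k] = mid @ model.state_utilities(age)
        if model.transition_costs is not None:
            cost[k] += float(occ[k] @ (P * model.transition_costs(age)).sum(axis=1))
        if model.transition_qalys is not None:
            qaly[k] += float(occ[k] @ (P * model.transition_qalys(age)).sum(axis=1))
    return CohortTrace(model.states, model.start_age, occ, cost, qaly)


def present_value(stream: Sequence[float], rate: float, offset_years: float = 0.0) -> float:
    """Discounted sum: sum_k stream[k] / (1+rate)^(k+offset_years).

    ``offset_years`` shifts a stream that starts later than the common base
    age so results from models with different start ages share one origin.
    """
    if not (0.0 <= rate < 1.0):
        raise MarkovError(f"rate outside [0,1): {rate}")
    if offset_years < 0:
        raise MarkovError("offset_years must be >= 0")
    s = np.asarray(stream, dtype=float)
    k = np.arange(s.size)
    return float(np.sum(s / (1.0 + rate) ** (k + offset_years)))
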