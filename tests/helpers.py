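"""Test helpers: an individual-level micro-simulation oracle for the cohort
engine, and random small-model generators.

The micro-simulation is an independent implementation path: it samples state
trajectories person by person and accrues rewards per individual with the
same mid-cycle convention the cohort engine uses in expectation, so cohort
traces must agree with it up to Monte Carlo error.
"""

from __future__ import annotations

import numpy as np

from ahc_cua.markov import MarkovModel


def micro_simulate(model: MarkovModel, pm, age_cap: int, n: int, rng: np.random.Generator):
    """Simulate ``n`` individuals; return per-cycle occupancy proportions and
    per-individual (undiscounted) cost/QALY totals."""
    n_states = len(model.states)
    cycles = age_cap - model.start_age
    states = rng.choice(n_states, size=n, p=model.initial_occupancy)
    occ = np.zeros((cycles + 1, n_states))
    occ[0] = np.bincount(states, minlength=n_states) / n
    cost = np.zeros(n)
    qaly = np.zeros(n)
    for k in range(cycles):
        age = model.start_age + k
        P = np.asarray(model.transition_rule(age, pm), dtype=float)
        cum = np.cumsum(P, axis=1)
        u = rng.random(n)
        nxt = np.empty(n, dtype=int)
        for s in np.unique(states):
            mask = states == s
            nxt[mask] = np.searchsorted(cum[s], u[mask], side="right")
        nxt = np.minimum(nxt, n_states - 1)
        c = model.state_costs(age)
        q = model.state_utilities(age)
        cost += 0.5 * (c[states] + c[nxt])
        qaly += 0.5 * (q[states] + q[nxt])
        if model.transition_costs is not None:
            cost += model.transition_costs(age)[states, nxt]
        if model.transition_qalys is not None:
            qaly += model.transition_qalys(age)[states, nxt]
        states = nxt
        occ[k + 1] = np.bincount(states, minlength=n_states) / n
    return occ, cost, qaly


def random_small_model(rng: np.random.Generator, n_states: int, start_age: int = 40) -> tuple:
    """A random n-state model with one absorbing death state and a fixed
    (age-independent) transition matrix. Returns (model, parameter_map)."""
    P = rng.dirichlet(np.full(n_states, 0.8), size=n_states)
    P[-1] = 0.0
    P[-1, -1] = 1.0  # Dead absorbing
    costs = np.round(rng.uniform(0, 500, n_states), 2)
    utils = np.round(rng.uniform(0, 1, n_states), 3)
    costs[-1] = 0.0
    utils[-1] = 0.0
    tc = np.round(rng.uniform(0, 100, (n_states, n_states)) * (rng.random((n_states, n_states)) < 0.3), 2)
    init = rng.dirichlet(np.full(n_states, 1.0))
    states = tuple(f"S{i}" for i in range(n_states - 1)) + ("Dead",)
    model = MarkovModel(
        states=states,
        transition_rule=lambda age, pm: P,
        state_costs=lambda age: costs,
        state_utilities=lambda age: utils,
        start_age=start_age,
        initial_occupancy=init,
        transition_costs=lambda age: tc,
    )
    return model, {}
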