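"""Probabilistic and one-way sensitivity analysis.

One root seed spawns an independent, counter-derived substream per Monte
Carlo draw, so results are reproducible and draws can be re-derived from
(seed, draw index) alone. Each draw samples every parameter once and
evaluates all condition models plus the intervention annuity with that
single draw.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .conditions import ModelContext
from .economics import ceac as _ceac
from .economics import evaluate_strategy, icer
from .parameters import DEFAULT_INTERPRETATION, ParameterSet, sample_parameters

log = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (20_000.0, 30_000.0)


class PSAError(ValueError):
    pass


@dataclass(frozen=True)
class PSADraw:
    draw_index: int
    inc_cost: float
    inc_qaly: float
    icer_value: float  # nan when flagged
    icer_flag: str


@dataclass(frozen=True)
class PSASummary:
    n_draws: int
    seed: int
    mean_inc_cost: float
    sd_inc_cost: float
    ci_inc_cost: tuple[float, float]
    mean_inc_qaly: float
    sd_inc_qaly: float
    ci_inc_qaly: tuple[float, float]
    mean_icer: float  # mean of per-draw ratios over finite draws
    ci_icer: tuple[float, float]
    icer_of_means: float  # ratio-of-means statistic
    n_icer_excluded: int
    ceac: tuple[tuple[float, float], ...]
    draws: pd.DataFrame = field(repr=False, compare=False)

    def to_dict(self) -> dict:
        return {
            "n_draws": self.n_draws,
            "seed": self.seed,
            "inc_cost": {
                "mean": self.mean_inc_cost,
                "sd": self.sd_inc_cost,
                "ci95": list(self.ci_inc_cost),
            },
            "inc_qaly": {
                "mean": self.mean_inc_qaly,
                "sd": self.sd_inc_qaly,
                "ci95": list(self.ci_inc_qaly),
            },
            "icer": {
                "mean_of_ratios": self.mean_icer,
                "ci95": list(self.ci_icer),
                "ratio_of_means": self.icer_of_means,
                "n_excluded": self.n_icer_excluded,
            },
            "ceac": [{"threshold": t, "p_cost_effective": p} for t, p in self.ceac],
        }


def _summarise(
    records: list[PSADraw], seed: int, thresholds: Sequence[float]
) -> PSASummary:
    df = pd.DataFrame(
        {
            "draw": [d.draw_index for d in records],
            "inc_cost": [d.inc_cost for d in records],
            "inc_qaly": [d.inc_qaly for d in records],
            "icer": [d.icer_value for d in records],
            "flag": [d.icer_flag for d in records],
        }
    )
    cost = df["inc_cost"].to_numpy()
    qaly = df["inc_qaly"].to_numpy()
    finite = df["icer"].to_numpy()
    finite = finite[np.isfinite(finite)]
    n_excluded = len(df) - finite.size
    if n_excluded:
        log.info(json.dumps({"event": "icer_draws_excluded", "n": int(n_excluded)}))
    pct = lambda a: (float(np.percentile(a, 2.5)), float(np.percentile(a, 97.5)))
    mean_qaly = float(qaly.mean())
    return PSASummary(
        n_draws=len(df),
        seed=seed,
        mean_inc_cost=float(cost.mean()),
        sd_inc_cost=float(cost.std(ddof=1)) if len(df) > 1 else 0.0,
        ci_inc_cost=pct(cost),
        mean_inc_qaly=mean_qaly,
        sd_inc_qaly=float(qaly.std(ddof=1)) if len(df) > 1 else 0.0,
        ci_inc_qaly=pct(qaly),
        mean_icer=float(finite.mean()) if finite.size else float("nan"),
        ci_icer=pct(finite) if finite.size else (float("nan"), float("nan")),
        icer_of_means=float(cost.mean() / mean_qaly) if mean_qaly != 0 else float("nan"),
        n_icer_excluded=int(n_excluded),
        ceac=tuple(_ceac(np.column_stack([cost, qaly]), thresholds)),
        draws=df,
    )


def run_psa(
    parameter_set: ParameterSet,
    n_draws: int,
    seed: int,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    ctx: ModelContext | None = None,
    interpretation: str = DEFAULT_INTERPRETATION,
) -> PSASummary:
    """Monte Carlo propagation of parameter uncertainty through the full
    multi-condition model."""
    if n_draws < 1:
        raise PSAError("n_draws must be >= 1")
    if ctx is None:
        ctx = ModelContext.default(parameter_set.metadata)
    streams = np.random.SeedSequence(seed).spawn(n_draws)
    records: list[PSADraw] = []
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        pm = sample_parameters(parameter_set, rng, interpretation)
        try:
            strat = evaluate_strategy(pm, ctx)
        except Exception as exc:
            raise PSAError(
                f"condition evaluation failed at draw {i}: {exc}; parameters: "
                + json.dumps(pm, default=float)
            ) from exc
        c, q = strat.inc_cost_total, strat.inc_qaly_total
        ic = icer(c, q)
        records.append(PSADraw(i, c, q, ic.value, ic.flag))
    return _summarise(records, seed, thresholds)


def one_way_sa(
    parameter_set: ParameterSet,
    parameter_name: str,
    values: Sequence[float],
    n_draws: int,
    seed: int,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    ctx: ModelContext | None = None,
    interpretation: str = DEFAULT_INTERPRETATION,
) -> pd.DataFrame:
    """One PSA per pinned value of one parameter, all other parameters at
    their PSA distributions, common seed across rows (common random
    numbers)."""
    if parameter_name not in parameter_set:
        raise PSAError(f"unknown parameter {parameter_name!r}")
    if len(values) == 0:
        raise PSAError("values must be non-empty")
    rows = []
    for v in values:
        pinned = parameter_set.pin(parameter_name, float(v))
        s = run_psa(pinned, n_draws, seed, thresholds, ctx, interpretation)
        row = {
            "value": float(v),
            "mean_inc_cost": s.mean_inc_cost,
            "mean_inc_qaly": s.mean_inc_qaly,
            "mean_icer": s.mean_icer,
            "icer_lo": s.ci_icer[0],
            "icer_hi": s.ci_icer[1],
        }
        for t, p in s.ceac:
            row[f"p_ce_{int(t)}"] = p
        rows.append(row)
    return pd.DataFrame(rows)


def ce_plane(draws: pd.DataFrame) -> pd.DataFrame:
    """Cost-effectiveness plane coordinates, one row per draw, order kept."""
    if len(draws) == 0:
        raise PSAError("empty draw set")
    return draws[["inc_qaly", "inc_cost"]].copy()
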