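"""Life tables and cohort survival.

Annual probabilities of death (qx) indexed by single year of age, with the
excess-mortality adjustment for intellectual disability and the survival
curves the cohort models and the intervention annuity are built on.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd


class LifeTableError(ValueError):
    pass


@dataclass(frozen=True)
class LifeTable:
    """Single-year life table: ``qx[i]`` is the probability of dying before
    the next birthday for a person aged ``ages[i]``. The terminal age is an
    absorbing cap (qx = 1)."""

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self):
        ages = np.asarray(self.ages, dtype=int)
        qx = np.asarray(self.qx, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "qx", qx)
        if ages.ndim != 1 or ages.size != qx.size or ages.size == 0:
            raise LifeTableError("ages and qx must be equal-length 1-d arrays")
        if np.any(np.diff(ages) != 1):
            raise LifeTableError("ages must be contiguous and ascending")
        if np.any((qx < 0) | (qx > 1)):
            raise LifeTableError("qx outside [0, 1]")
        if qx[-1] != 1.0:
            raise LifeTableError("terminal qx must be 1 (absorbing cap)")

    def q_at(self, age: int) -> float:
        lo, hi = int(self.ages[0]), int(self.ages[-1])
        if not lo <= age <= hi:
            raise LifeTableError(f"age {age} outside table coverage [{lo}, {hi}]")
        return float(self.qx[age - lo])

    def to_csv(self) -> str:
        # %.17g so qx round-trips through text exactly
        return pd.DataFrame({"age": self.ages, "qx": self.qx}).to_csv(
            index=False, float_format="%.17g"
        )


@dataclass(frozen=True)
class SurvivalCurve:
    """Probability of being alive at the beginning of each annual cycle."""

    start_age: int
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v[0] != 1.0 or np.any(np.diff(v) > 1e-12) or np.any((v < 0) | (v > 1)):
            raise LifeTableError("survival must start at 1, be non-increasing, in [0,1]")


def read_life_table(table_text: str) -> LifeTable:
    """Parse a two-column age,qx CSV (header optional)."""
    first = table_text.lstrip().splitlines()[0] if table_text.strip() else ""
    has_header = any(c.isalpha() for c in first)
    df = pd.read_csv(
        io.StringIO(table_text),
        header=0 if has_header else None,
        names=["age", "qx"] if not has_header else None,
        float_precision="round_trip",
    )
    if has_header:
        df = df.rename(columns={df.columns[0]: "age", df.columns[1]: "qx"})
    return LifeTable(df["age"].to_numpy(int), df["qx"].to_numpy(float))


def adjust_id_mortality(
    life_table: LifeTable, multiplier: float, scale: str = "probability"
) -> LifeTable:
    """Apply the excess-mortality multiplier for intellectual disability.

    ``probability`` scaling replaces qx by min(1, multiplier*qx); ``hazard``
    scaling uses 1-(1-qx)**multiplier (a sensitivity alternative).
    """
    if multiplier <= 0:
        raise LifeTableError("multiplier must be positive")
    if scale == "probability":
        qx = np.minimum(1.0, multiplier * life_table.qx)
    elif scale == "hazard":
        qx = 1.0 - (1.0 - life_table.qx) ** multiplier
    else:
        raise LifeTableError(f"unknown scale {scale!r}")
    qx[-1] = 1.0
    return LifeTable(life_table.ages.copy(), qx)


def survival_curve(life_table: LifeTable, start_age: int, age_cap: int) -> SurvivalCurve:
    """Cohort survival from ``start_age``: values[k] = prod_{j<k} (1-qx)."""
    if start_age < life_table.ages[0] or age_cap > life_table.ages[-1]:
        raise LifeTableError(
            f"[{start_age}, {age_cap}] not covered by table "
            f"[{life_table.ages[0]}, {life_table.ages[-1]}]"
        )
    q = np.array([life_table.q_at(a) for a in range(start_age, age_cap)])
    values = np.concatenate([[1.0], np.cumprod(1.0 - q)])
    return SurvivalCurve(start_age, values)
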