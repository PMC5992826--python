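"""Background all-cause mortality: the life table.

A :class:`LifeTable` holds one row per integer age with ``qx``, the annual
probability of dying from any cause between exact age x and x+1.  The cohort
model uses it for the competing other-cause mortality applied to every
living state.  Tables are exchanged as plain CSV with header ``age,qx``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .params import ParameterError

__all__ = ["LifeTable", "read_life_table", "write_life_table"]


@dataclass
class LifeTable:
    """Age-indexed annual all-cause death probabilities.

    Ages must be contiguous integers; the final row is the closure age, at
    which qx is forced to 1 so the population is extinguished.
    """

    ages: np.ndarray
    qx: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.qx = np.asarray(self.qx, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.ages.ndim != 1 or self.ages.shape != self.qx.shape:
            raise ParameterError("life table: ages and qx must be 1-D and aligned")
        if len(self.ages) < 2:
            raise ParameterError("life table: need at least two rows")
        if np.any(np.diff(self.ages) != 1):
            raise ParameterError("life table: ages must be contiguous integers")
        if np.any((self.qx < 0) | (self.qx > 1)):
            raise ParameterError("life table: qx outside [0, 1]")

    @property
    def min_age(self) -> int:
        return int(self.ages[0])

    @property
    def max_age(self) -> int:
        return int(self.ages[-1])

    def q(self, age: float) -> float:
        """qx at integer ``age``; ages beyond the last row die with certainty."""
        a = int(age)
        if a < self.min_age:
            raise ParameterError(f"life table: age {age} below table start")
        if a > self.max_age:
            return 1.0
        return float(self.qx[a - self.min_age])

    def survival_from(self, age: int) -> np.ndarray:
        """S(t) = P(alive at age+t | alive at age), t = 0..(max_age-age+1)."""
        a0 = int(age) - self.min_age
        if a0 < 0:
            raise ParameterError(f"life table: age {age} below table start")
        q = self.qx[a0:]
        return np.concatenate([[1.0], np.cumprod(1.0 - q)])

    def life_expectancy(self, age: int = 0) -> float:
        """Remaining life expectancy by the standard life-table method
        (deaths spread uniformly within the year: ax = 0.5)."""
        s = self.survival_from(age)
        return float(s[1:].sum() + 0.5)


def read_life_table(path: str | Path) -> LifeTable:
    """Read a CSV with columns ``age`` and ``qx``; rows sorted, validated."""
    df = pd.read_csv(path)
    missing = {"age", "qx"} - set(df.columns)
    if missing:
        raise ParameterError(f"life table {path}: missing columns {sorted(missing)}")
    df = df.sort_values("age")
    ages = df["age"].to_numpy()
    if len(np.unique(ages)) != len(ages):
        raise ParameterError(f"life table {path}: duplicated age rows")
    if np.any(ages != ages.astype(int)):
        raise ParameterError(f"life table {path}: ages must be integers")
    return LifeTable(ages=ages.astype(int), qx=df["qx"].to_numpy())


def write_life_table(table: LifeTable, path: str | Path) -> None:
    pd.DataFrame({"age": table.ages, "qx": table.qx}).to_csv(path, index=False)
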