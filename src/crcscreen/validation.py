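"""Model validation: predicted clinical incidence by age.

Runs the no-screening cohort and converts new clinical diagnoses per cycle
into an annual rate per 100,000 living persons, the quantity cancer
registries publish, so the model curve can be compared qualitatively with
registry data supplied as a CSV (``age,incidence_per_100k``).  No registry
values are bundled.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import run_cohort
from .life_tables import LifeTable
from .params import ParameterError, ParameterSet

__all__ = ["IncidenceCurve", "predicted_incidence_curve", "read_registry_curve",
           "compare_to_registry"]


@dataclass
class IncidenceCurve:
    ages: np.ndarray
    incidence_per_100k: np.ndarray

    def __post_init__(self) -> None:
        self.ages = np.asarray(self.ages, dtype=int)
        self.incidence_per_100k = np.asarray(self.incidence_per_100k, dtype=float)
        if self.ages.shape != self.incidence_per_100k.shape:
            raise ParameterError("incidence curve: ages and values misaligned")
        if np.any(~np.isfinite(self.incidence_per_100k)) or np.any(
            self.incidence_per_100k < 0
        ):
            raise ParameterError("incidence curve: values must be finite and >= 0")

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "incidence_per_100k": self.incidence_per_100k}
        )


def predicted_incidence_curve(
    params: ParameterSet, life_table: LifeTable, max_age: int = 85
) -> IncidenceCurve:
    """Annual clinical CRC incidence per 100,000 by age under no screening."""
    res = run_cohort(params, None, life_table)
    mask = res.ages <= max_age
    return IncidenceCurve(
        ages=res.ages[mask], incidence_per_100k=res.incidence_by_age[mask]
    )


def read_registry_curve(path: str | Path) -> IncidenceCurve:
    df = pd.read_csv(path)
    missing = {"age", "incidence_per_100k"} - set(df.columns)
    if missing:
        raise ParameterError(f"registry file: missing columns {sorted(missing)}")
    df = df.sort_values("age")
    return IncidenceCurve(
        ages=df["age"].to_numpy(), incidence_per_100k=df["incidence_per_100k"].to_numpy()
    )


def compare_to_registry(curve: IncidenceCurve, registry: IncidenceCurve) -> dict:
    """Difference summaries on the common age support."""
    common = np.intersect1d(curve.ages, registry.ages)
    if common.size == 0:
        raise ParameterError("no overlapping ages between model and registry curves")
    a = curve.incidence_per_100k[np.isin(curve.ages, common)]
    b = registry.incidence_per_100k[np.isin(registry.ages, common)]
    diff = a - b
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(b > 0, np.abs(diff) / b, np.nan)
    return {
        "n_ages": int(common.size),
        "max_abs_difference": float(np.max(np.abs(diff))),
        "mean_relative_difference": float(np.nanmean(rel)),
    }
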