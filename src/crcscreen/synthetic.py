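"""Synthetic inputs: life tables, sampled parameter sets, toy oracles.

The national life table the model needs is not bundled; this module
generates a synthetic stand-in from a Gompertz–Makeham hazard
mu(age) = a + b * exp(c * age), discretized exactly over each year of age:
qx = 1 - exp(-integral of mu over [x, x+1)), so the discrete survival
curve coincides with the continuous survival function at integer ages.
The default coefficients are calibrated to two published demographic
anchors for Ukraine 2013 — life expectancy ~71 years at birth and ~25
years at age 50
(the country's adult survival is poor relative to its infant survival, so a
single-anchor fit would be far too optimistic after 50).

Also here: uniform sampling of parameter sets within their declared
sensitivity ranges, and a three-state toy model (well → sick → dead at
constant rates) with geometric-series closed forms for expected discounted
occupancy, used to verify the cohort engine to machine accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .life_tables import LifeTable
from .params import AgeSchedule, ParameterError, ParameterSet, get_param, set_param

__all__ = [
    "LifeTableSpec",
    "DEFAULT_LIFE_TABLE_SPEC",
    "synthetic_life_table",
    "default_life_table",
    "sample_parameter_set",
    "toy_three_state_model",
]


@dataclass(frozen=True)
class LifeTableSpec:
    """Gompertz–Makeham hazard parameters for a synthetic life table."""

    makeham_a: float = 7.98e-4  # age-independent background hazard /year
    gompertz_b: float = 5.13e-5  # senescent hazard scale /year
    gompertz_c: float = 0.095  # log-hazard slope /year of age
    max_age: int = 110

    def validate(self) -> "LifeTableSpec":
        if self.makeham_a < 0 or self.gompertz_b < 0:
            raise ParameterError("life-table spec: hazards must be >= 0")
        if self.gompertz_c < 0:
            raise ParameterError("life-table spec: slope must be >= 0")
        if self.max_age < 1:
            raise ParameterError("life-table spec: max_age must be >= 1")
        return self


DEFAULT_LIFE_TABLE_SPEC = LifeTableSpec()


def synthetic_life_table(spec: LifeTableSpec = DEFAULT_LIFE_TABLE_SPEC) -> LifeTable:
    """Deterministic life table from the hazard spec.

    qx = 1 - exp(-H) is bounded in [0, 1) for any nonnegative hazard, so no
    clamping can trigger before the closure age, where qx is forced to 1.
    """
    spec.validate()
    ages = np.arange(0, spec.max_age + 1)
    a, b, c = spec.makeham_a, spec.gompertz_b, spec.gompertz_c
    if c > 0:
        # exact integral of the hazard over each year of age
        cum_hazard = a + (b / c) * np.exp(c * ages) * (np.exp(c) - 1.0)
    else:
        cum_hazard = np.full_like(ages, a + b, dtype=float)
    qx = 1.0 - np.exp(-cum_hazard)
    qx[-1] = 1.0
    return LifeTable(ages=ages, qx=qx)


def default_life_table() -> LifeTable:
    """The shipped synthetic Ukraine-like table (e0 ~ 71 y, e50 ~ 25 y)."""
    return synthetic_life_table(DEFAULT_LIFE_TABLE_SPEC)


def sample_parameter_set(seed: int, params: ParameterSet) -> ParameterSet:
    """Independent uniform draws within every declared sensitivity range.

    Age-schedule ranges are factor intervals, so the draw scales all
    anchors.  Reproducible: the same seed yields the same set.
    """
    rng = np.random.default_rng(seed)
    out = params
    for pid in sorted(params.ranges):
        lo, hi = params.ranges[pid]
        value = float(rng.uniform(lo, hi)) if hi > lo else _base_value(params, pid, lo)
        out = set_param(out, pid, value)
    return out


def _base_value(params: ParameterSet, pid: str, lo: float) -> float:
    current = get_param(params, pid)
    if isinstance(current, AgeSchedule):
        return lo  # zero-width factor interval
    return lo


def toy_three_state_model(
    p: float = 0.05, q: float = 0.30, u_well: float = 1.0, u_sick: float = 0.6,
    c_well: float = 0.0, c_sick: float = 1000.0,
):
    """Well → sick → dead chain with constant rates and per-cycle payoffs.

    Returns ``(P, init, utilities, costs, analytic)`` where ``analytic(T,
    rate)`` gives the exact discounted QALYs and costs of a cohort started
    well and run for T cycles with cycle-start accounting, from the finite
    geometric sums of the occupancy series:

        well(t) = (1-p)^t
        sick(t) = p * ((1-q)^t - (1-p)^t) / (p - q)        (p != q)
    """
    if not (0 < p < 1 and 0 < q <= 1) or p == q:
        raise ParameterError("toy model needs 0 < p < 1, 0 < q <= 1, p != q")
    P = np.array(
        [
            [1.0 - p, p, 0.0],
            [0.0, 1.0 - q, q],
            [0.0, 0.0, 1.0],
        ]
    )
    init = np.array([1.0, 0.0, 0.0])
    utilities = np.array([u_well, u_sick, 0.0])
    costs = np.array([c_well, c_sick, 0.0])

    def geom(x: float, T: int) -> float:
        if x == 1.0:
            return float(T)
        return (1.0 - x**T) / (1.0 - x)

    def analytic(T: int, rate: float) -> dict:
        v = 1.0 / (1.0 + rate)
        w_sum = geom(v * (1.0 - p), T)
        s_sum = p / (p - q) * (geom(v * (1.0 - q), T) - geom(v * (1.0 - p), T))
        return {
            "discounted_qalys": u_well * w_sum + u_sick * s_sum,
            "discounted_cost": c_well * w_sum + c_sick * s_sum,
        }

    return P, init, utilities, costs, analytic
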