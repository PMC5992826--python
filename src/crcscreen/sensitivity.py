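"""Deterministic sensitivity analyses over the screening pipeline.

One-way sweeps move a single parameter across its declared range with all
others at base case; the tornado ranks parameters by the span of a summary
metric between their range endpoints; threshold search bisects a parameter
until the preferred strategy flips (recovering e.g. the colonoscopy cost
above which, or the colonoscopy adherence below which, the 10-yearly
colonoscopy program stops being optimal); multi-way analysis evaluates a
full factorial grid; and the decreased-treatment-adherence scenario lowers
the probability that diagnosed patients receive treatment to the level
reported for Ukraine (75 %).

Parameters are addressed by dotted ids (see ``params``); age-schedule ids
are swept by a multiplicative factor on all anchors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cea import CEATable, cea_table, optimal_strategy, wtp_threshold
from .cohort import run_cohort
from .life_tables import LifeTable
from .params import ParameterError, ParameterSet, set_param
from .screening import COLO_10, NO_SCREENING, StrategySpec, builtin_strategies

__all__ = [
    "PipelineOutcome",
    "SweepResult",
    "ThresholdResult",
    "evaluate_pipeline",
    "one_way",
    "tornado",
    "threshold_search",
    "multi_way",
    "scenario_low_treatment_adherence",
]


@dataclass
class PipelineOutcome:
    """Full CEA of all strategies at one parameter point."""

    table: CEATable
    wtp: float
    optimal: str

    def net_benefit(self, name: str) -> float:
        row = self.table.row(name)
        return self.wtp * row.qalys - row.cost

    def nmb_margin(self, name: str = COLO_10) -> float:
        """Net-monetary-benefit margin of ``name`` over the best of the
        other strategies at the WTP threshold (positive when preferred)."""
        others = [r.name for r in self.table.rows if r.name != name]
        return self.net_benefit(name) - max(self.net_benefit(o) for o in others)

    def icer_vs_next_best(self, name: str = COLO_10):
        return self.table.row(name).icer_vs_next_best


def evaluate_pipeline(
    params: ParameterSet,
    life_table: LifeTable,
    strategies: list[StrategySpec] | None = None,
) -> PipelineOutcome:
    """Run every strategy and rank them; the one full model evaluation all
    sensitivity machinery is built from."""
    if strategies is None:
        strategies = builtin_strategies(params.econ)
    results = [run_cohort(params, s, life_table) for s in strategies]
    table = cea_table(results, baseline_name=NO_SCREENING)
    wtp = wtp_threshold(params.econ.gdp_per_capita)
    return PipelineOutcome(table=table, wtp=wtp, optimal=optimal_strategy(table, wtp))


@dataclass
class SweepResult:
    param_id: str
    values: np.ndarray
    outcomes: list[PipelineOutcome]

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "value": self.values,
                "optimal": [o.optimal for o in self.outcomes],
                "nmb_margin_colo10": [o.nmb_margin(COLO_10) for o in self.outcomes],
            }
        )


def _resolve_range(params: ParameterSet, param_id: str) -> tuple[float, float]:
    if param_id not in params.ranges:
        raise ParameterError(f"parameter {param_id!r} has no declared range")
    return params.ranges[param_id]


def one_way(
    param_id: str,
    params: ParameterSet,
    life_table: LifeTable,
    n_points: int = 11,
    value_range: tuple[float, float] | None = None,
    strategies: list[StrategySpec] | None = None,
) -> SweepResult:
    """Evaluate the full pipeline on an evenly spaced grid over the
    parameter's range, all other parameters at base case."""
    if n_points < 2:
        raise ParameterError("one_way needs n_points >= 2")
    lo, hi = value_range if value_range is not None else _resolve_range(params, param_id)
    values = np.linspace(lo, hi, n_points)
    outcomes = [
        evaluate_pipeline(set_param(params, param_id, v), life_table, strategies)
        for v in values
    ]
    return SweepResult(param_id=param_id, values=values, outcomes=outcomes)


def tornado(
    params: ParameterSet,
    life_table: LifeTable,
    param_ids: list[str] | None = None,
    metric: str = "nmb_margin",
    strategies: list[StrategySpec] | None = None,
) -> pd.DataFrame:
    """Metric at each parameter's range endpoints, ranked by span.

    ``metric``: ``nmb_margin`` (net monetary benefit of the 10-yearly
    colonoscopy program over the best alternative at the WTP threshold) or
    ``icer`` (its ICER vs the next-best non-dominated strategy; dominance
    codes map to 0 for span purposes).
    """
    if metric not in ("nmb_margin", "icer"):
        raise ParameterError(f"unknown tornado metric {metric!r}")
    ids = param_ids if param_ids is not None else sorted(params.ranges)
    if not ids:
        raise ParameterError("tornado: no parameters to vary")

    def measure(outcome: PipelineOutcome) -> float:
        if metric == "nmb_margin":
            return outcome.nmb_margin(COLO_10)
        ic = outcome.icer_vs_next_best(COLO_10)
        return float(ic) if isinstance(ic, (int, float)) else 0.0

    rows = []
    for pid in ids:
        lo, hi = _resolve_range(params, pid)
        m_lo = measure(evaluate_pipeline(set_param(params, pid, lo), life_table, strategies))
        m_hi = measure(evaluate_pipeline(set_param(params, pid, hi), life_table, strategies))
        rows.append(
            {
                "param_id": pid,
                "low_value": lo,
                "high_value": hi,
                "metric_at_low": m_lo,
                "metric_at_high": m_hi,
                "span": abs(m_hi - m_lo),
            }
        )
    df = pd.DataFrame(rows).sort_values("span", ascending=False, kind="mergesort")
    return df.reset_index(drop=True)


@dataclass
class ThresholdResult:
    param_id: str
    breakpoint: float
    below: str  # decision on the low side of the breakpoint
    above: str  # decision on the high side
    bracket: tuple[float, float]
    tolerance: float


def threshold_search(
    param_id: str,
    bounds: tuple[float, float],
    params: ParameterSet,
    life_table: LifeTable,
    decision=None,
    tolerance: float | None = None,
    strategies: list[StrategySpec] | None = None,
) -> ThresholdResult:
    """Bisect ``param_id`` between ``bounds`` until the decision flips
    within ``tolerance``; the breakpoint is the bracket midpoint.

    ``decision`` maps a :class:`PipelineOutcome` to a hashable label; the
    default is the optimal strategy's name.  Default tolerances: $1 for cost
    parameters, 0.005 otherwise.
    """
    if decision is None:
        decision = lambda outcome: outcome.optimal  # noqa: E731
    if tolerance is None:
        tolerance = 1.0 if param_id.startswith("costs.") else 0.005
    lo, hi = float(bounds[0]), float(bounds[1])
    if not lo < hi:
        raise ParameterError("threshold_search: bounds must satisfy low < high")

    def dec(v: float):
        return decision(
            evaluate_pipeline(set_param(params, param_id, v), life_table, strategies)
        )

    d_lo, d_hi = dec(lo), dec(hi)
    if d_lo == d_hi:
        raise ParameterError(
            f"threshold_search: decision {d_lo!r} identical at both bounds"
        )
    while hi - lo > tolerance:
        mid = 0.5 * (lo + hi)
        if dec(mid) == d_lo:
            lo = mid
        else:
            hi = mid
    return ThresholdResult(
        param_id=param_id,
        breakpoint=0.5 * (lo + hi),
        below=d_lo,
        above=d_hi,
        bracket=(lo, hi),
        tolerance=tolerance,
    )


def multi_way(
    param_ids: list[str],
    grids: list[np.ndarray],
    params: ParameterSet,
    life_table: LifeTable,
    strategies: list[StrategySpec] | None = None,
    max_cells: int = 2000,
) -> pd.DataFrame:
    """Full-factorial evaluation over 2 or 3 parameters; each cell records
    the optimal strategy at the WTP threshold."""
    if not (2 <= len(param_ids) <= 3):
        raise ParameterError("multi_way takes 2 or 3 parameter ids")
    if len(grids) != len(param_ids):
        raise ParameterError("multi_way: one grid per parameter id")
    mesh = np.meshgrid(*[np.asarray(g, dtype=float) for g in grids], indexing="ij")
    n_cells = mesh[0].size
    if n_cells > max_cells:
        raise ParameterError(f"multi_way grid has {n_cells} cells (> {max_cells})")
    rows = []
    for idx in np.ndindex(mesh[0].shape):
        point = params
        record = {}
        for pid, m in zip(param_ids, mesh):
            v = float(m[idx])
            point = set_param(point, pid, v)
            record[pid] = v
        outcome = evaluate_pipeline(point, life_table, strategies)
        record["optimal"] = outcome.optimal
        rows.append(record)
    return pd.DataFrame(rows)


def scenario_low_treatment_adherence(
    params: ParameterSet, treatment_receipt: float = 0.75
) -> ParameterSet:
    """The decreased-treatment-adherence scenario: only ``treatment_receipt``
    of diagnosed patients receive treatment (Ukraine: 25 % receive none);
    untreated patients follow the untreated mortality policy.  All other
    parameters stay at their input values."""
    new = params.copy()
    new.mortality.treatment_receipt_probability = float(treatment_receipt)
    return new.validate()
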