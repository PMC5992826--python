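"""Incremental cost-effectiveness comparison of screening strategies.

Strategies are ranked on the cost–QALY plane.  A strategy is strictly
dominated when another is at least as cheap and at least as effective (one
strictly); among the survivors, extended dominance removes any strategy
whose ICER over the previous frontier point exceeds the ICER of the next
segment (equivalently, the frontier is the lower-left convex hull).  ICERs
are computed against the next-best non-dominated comparator.  The optimal
strategy at a willingness-to-pay (WTP) threshold — three times per-capita
GDP here — is the frontier strategy with the highest ICER not exceeding
the threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .cohort import CohortResult, crc_mortality_reduction
from .params import ParameterError

__all__ = [
    "DOMINANT",
    "DOMINATED",
    "EXT_DOMINATED",
    "ON_FRONTIER",
    "EQUIVALENT",
    "StrategyRow",
    "CEATable",
    "icer",
    "cea_table",
    "wtp_threshold",
    "optimal_strategy",
]

DOMINANT = "dominant"
DOMINATED = "dominated"
EXT_DOMINATED = "extendedly-dominated"
ON_FRONTIER = "on-frontier"
EQUIVALENT = "equivalent"


def icer(delta_cost: float, delta_effect: float):
    """Incremental cost-effectiveness ratio, or a dominance code.

    For a pair ordered by effect: the ratio when both increments are
    positive; DOMINANT when the more effective option is also cheaper;
    DOMINATED when it is costlier and less effective.  A pure cost
    difference at equal effect is reported as such, never as a ratio.
    """
    if delta_cost == 0 and delta_effect == 0:
        return EQUIVALENT
    if delta_effect == 0:
        return DOMINANT if delta_cost < 0 else DOMINATED
    if delta_effect > 0:
        return DOMINANT if delta_cost <= 0 else delta_cost / delta_effect
    return DOMINATED if delta_cost >= 0 else -delta_cost / -delta_effect


@dataclass
class StrategyRow:
    name: str
    cost: float
    qalys: float
    status: str
    icer_vs_next_best: float | str | None
    # incrementals against the overall best (cheapest most-effective) strategy
    inc_cost_vs_best: float | None
    inc_qalys_vs_best: float | None
    mortality_reduction_pct: float | None


@dataclass
class CEATable:
    rows: list[StrategyRow]
    frontier: list[str]
    best: str

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "strategy": r.name,
                    "cost": r.cost,
                    "qalys": r.qalys,
                    "incremental_cost_vs_best": r.inc_cost_vs_best,
                    "incremental_qalys_vs_best": r.inc_qalys_vs_best,
                    "status": r.status,
                    "icer": r.icer_vs_next_best,
                    "mortality_reduction_pct": r.mortality_reduction_pct,
                }
                for r in self.rows
            ]
        )

    def row(self, name: str) -> StrategyRow:
        for r in self.rows:
            if r.name == name:
                return r
        raise ParameterError(f"no strategy {name!r} in CEA table")


def _frontier(points: list[tuple[str, float, float]]) -> list[str]:
    """Non-dominated frontier (strict then extended dominance), names in
    ascending-cost order.  ``points`` are (name, cost, qalys)."""
    # strict dominance
    alive = []
    for name, c, q in points:
        dominated = any(
            (c2 <= c and q2 >= q and (c2 < c or q2 > q))
            for n2, c2, q2 in points
            if n2 != name
        )
        if not dominated:
            alive.append((name, c, q))
    # coincident points are co-optimal: run the hull on unique coordinates
    groups: dict[tuple[float, float], list[str]] = {}
    for name, c, q in alive:
        groups.setdefault((c, q), []).append(name)
    pts = sorted(groups)  # strictly increasing cost AND qalys after strict dominance
    # extended dominance: keep the lower-left convex hull; a middle point is
    # removed only when its ICER strictly exceeds the next segment's
    hull: list[tuple[float, float]] = []
    for c3, q3 in pts:
        while len(hull) >= 2:
            (c1, q1), (c2, q2) = hull[-2], hull[-1]
            icer12 = (c2 - c1) / (q2 - q1) if q2 != q1 else math.inf
            icer13 = (c3 - c1) / (q3 - q1) if q3 != q1 else math.inf
            if icer12 > icer13:
                hull.pop()
            else:
                break
        hull.append((c3, q3))
    return [name for pt in hull for name in groups[pt]]


def cea_table(
    results: list[CohortResult], baseline_name: str = "NO_SCREENING"
) -> CEATable:
    """Build the ranked incremental comparison with dominance labels.

    Mortality reductions are reported against ``baseline_name`` when that
    strategy is present.
    """
    names = [r.strategy for r in results]
    if len(results) < 2:
        raise ParameterError("need at least two strategies to compare")
    if len(set(names)) != len(names):
        raise ParameterError("duplicate strategy names in CEA input")
    points = [(r.strategy, r.discounted_cost, r.discounted_qalys) for r in results]
    frontier = _frontier(points)
    by_name = {r.strategy: r for r in results}

    baseline = by_name.get(baseline_name)

    # the "best" strategy: most effective frontier point (ties -> cheapest)
    frontier_pts = [(n, by_name[n].discounted_cost, by_name[n].discounted_qalys)
                    for n in frontier]
    best = max(frontier_pts, key=lambda t: (t[2], -t[1]))[0]

    strictly_alive = set()
    for name, c, q in points:
        dominated = any(
            (c2 <= c and q2 >= q and (c2 < c or q2 > q))
            for n2, c2, q2 in points
            if n2 != name
        )
        if not dominated:
            strictly_alive.add(name)

    rows = []
    order = sorted(results, key=lambda r: (r.discounted_cost, -r.discounted_qalys))
    for res in order:
        name = res.strategy
        if name in frontier:
            idx = frontier.index(name)
            if idx == 0:
                ic = None  # reference: cheapest frontier strategy
            else:
                prev = by_name[frontier[idx - 1]]
                ic = icer(
                    res.discounted_cost - prev.discounted_cost,
                    res.discounted_qalys - prev.discounted_qalys,
                )
            dominates_all = all(
                res.discounted_cost <= o.discounted_cost
                and res.discounted_qalys >= o.discounted_qalys
                for o in results
                if o.strategy != name
            )
            status = DOMINANT if dominates_all else ON_FRONTIER
        elif name in strictly_alive:
            status = EXT_DOMINATED
            ic = None
        else:
            status = DOMINATED
            ic = None
        best_res = by_name[best]
        mort = None
        if baseline is not None and baseline.lifetime_crc_deaths > 0:
            mort = (
                None
                if name == baseline_name
                else crc_mortality_reduction(res, baseline)
            )
        rows.append(
            StrategyRow(
                name=name,
                cost=res.discounted_cost,
                qalys=res.discounted_qalys,
                status=status,
                icer_vs_next_best=ic,
                inc_cost_vs_best=(
                    None if name == best else res.discounted_cost - best_res.discounted_cost
                ),
                inc_qalys_vs_best=(
                    None if name == best else res.discounted_qalys - best_res.discounted_qalys
                ),
                mortality_reduction_pct=mort,
            )
        )
    return CEATable(rows=rows, frontier=frontier, best=best)


def wtp_threshold(gdp_per_capita: float) -> float:
    """Willingness to pay per QALY: three times per-capita GDP."""
    if gdp_per_capita <= 0:
        raise ParameterError("gdp_per_capita must be > 0")
    return 3.0 * gdp_per_capita


def optimal_strategy(table: CEATable, wtp: float) -> str:
    """Frontier strategy with the highest ICER at or below ``wtp``; when
    every ICER exceeds it, the least costly frontier strategy."""
    if not table.rows:
        raise ParameterError("empty CEA table")
    choice = table.frontier[0]
    for name in table.frontier[1:]:
        ic = table.row(name).icer_vs_next_best
        if isinstance(ic, str):  # dominance code: strictly better than prev
            choice = name
        elif ic is not None and ic <= wtp:
            choice = name
        else:
            break
    return choice
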