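"""Lifetime cohort runs: one strategy, discounted costs and QALYs.

The engine iterates 1-year cycles from the cohort entry age (50) to the
terminal age (100), each cycle applying, in fixed order: the screening
operator (when the strategy offers tests that year), the natural-history
transition, and payoff accrual.  Accounting is cycle-start (no half-cycle
correction): utilities and annual state costs are accrued on the
post-screening occupancy, screening costs on the round actually performed,
and treatment costs once on entry into a clinical state — whether entry
happens through screen detection or clinical presentation.  All payoffs are
discounted to the entry age at the annual rate.

The inner loop (:func:`run_markov`) is a plain discounted Markov
accumulator over an arbitrary state basis, so it can be exercised directly
against closed-form toy models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .life_tables import LifeTable
from .natural_history import (
    CLIN_DISTANT_STATES,
    CLIN_LOCAL_STATES,
    CLIN_REGIONAL_STATES,
    CLINICAL_STATES,
    HealthState,
    InternalState,
    N_INTERNAL,
    TUNNEL_STATES,
    aggregate_to_public,
    build_transition_matrix,
    initial_distribution,
)
from .params import ParameterError, ParameterSet
from .screening import StrategySpec, apply_screening_cycle

__all__ = [
    "CohortResult",
    "discount_factor",
    "run_markov",
    "run_cohort",
    "crc_mortality_reduction",
]

_S = InternalState
_CLINICAL = CLINICAL_STATES
_SURV_STATES = TUNNEL_STATES + (_S.SURVEILLANCE,)


def discount_factor(year_index: int, rate: float) -> float:
    """(1 + rate)^(-year_index); year 0 is the cohort entry age."""
    if year_index < 0:
        raise ParameterError("year_index must be >= 0")
    if rate < 0:
        raise ParameterError("discount rate must be >= 0")
    return float((1.0 + rate) ** (-year_index))


def run_markov(
    init: np.ndarray,
    kernel,
    n_cycles: int,
    rate: float,
    utilities: np.ndarray,
    state_costs: np.ndarray,
    entry_costs: np.ndarray | None = None,
    screening=None,
    mass_tol: float = 1e-9,
):
    """Discounted cohort accumulation over an arbitrary Markov chain.

    ``kernel(t)`` returns the transition matrix for cycle ``t``;
    ``screening(t, x)``, if given, returns ``(x', cost, entries)`` where
    ``entries`` is the per-state inflow vector caused by the operator.
    Entry costs are charged on all inflows into a state within a cycle
    (kernel inflows exclude the diagonal).  Returns a dict of traces and
    discounted/undiscounted totals.
    """
    n = len(init)
    x = np.asarray(init, dtype=float).copy()
    trace = np.zeros((n_cycles + 1, n))
    entries = np.zeros((n_cycles, n))
    screen_cost_by_cycle = np.zeros(n_cycles)
    disc_cost = undisc_cost = disc_qaly = undisc_qaly = 0.0
    entry_costs = np.zeros(n) if entry_costs is None else np.asarray(entry_costs)

    for t in range(n_cycles):
        trace[t] = x
        v = discount_factor(t, rate)
        cycle_cost = 0.0
        if screening is not None:
            x, sc, screen_entries = screening(t, x)
            cycle_cost += sc + float(screen_entries @ entry_costs)
            entries[t] += screen_entries
            screen_cost_by_cycle[t] = sc
        cycle_cost += float(state_costs @ x)
        qaly = float(utilities @ x)
        P = kernel(t)
        inflow = x @ P - x * np.diag(P)
        entries[t] += inflow
        cycle_cost += float(inflow @ entry_costs)
        disc_cost += v * cycle_cost
        undisc_cost += cycle_cost
        disc_qaly += v * qaly
        undisc_qaly += qaly
        x = x @ P
        total = x.sum()
        if abs(total - 1.0) > mass_tol:
            raise ParameterError(
                f"cohort trace lost mass at cycle {t}: sum={total:.12f}"
            )
        x = x / total
    trace[n_cycles] = x
    return {
        "trace": trace,
        "entries": entries,
        "screen_cost_by_cycle": screen_cost_by_cycle,
        "discounted_cost": disc_cost,
        "undiscounted_cost": undisc_cost,
        "discounted_qalys": disc_qaly,
        "undiscounted_qalys": undisc_qaly,
        "final": x,
    }


@dataclass
class CohortResult:
    """Per-strategy lifetime outcomes for one cohort member."""

    strategy: str
    ages: np.ndarray
    trace_public: np.ndarray  # (n_cycles+1, 12) occupancy at cycle start
    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    lifetime_crc_deaths: float
    lifetime_clinical_cases: float  # cumulative clinical diagnoses /person
    incidence_by_age: np.ndarray  # new clinical cases per 100,000 living/year
    expected_colonoscopies: float
    expected_perforation_deaths: float

    def trace_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.trace_public,
            columns=[s.name for s in HealthState],
        )
        df.insert(0, "age", np.append(self.ages, self.ages[-1] + 1))
        return df

    def incidence_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"age": self.ages, "incidence_per_100k": self.incidence_by_age}
        )


def _payoff_vectors(params: ParameterSet):
    u = np.zeros(N_INTERNAL)
    uh = params.utilities.u_healthy_and_polyp_states
    for s in (
        _S.NORMAL,
        _S.LOW_POLYP,
        _S.HIGH_POLYP,
        _S.PRECLIN_LOCAL,
        _S.PRECLIN_REGIONAL,
        _S.PRECLIN_DISTANT,
    ):
        u[s] = uh
    ulr = params.utilities.u_local_regional_cancer
    for s in CLIN_LOCAL_STATES + CLIN_REGIONAL_STATES + TUNNEL_STATES:
        u[s] = ulr
    for s in CLIN_DISTANT_STATES:
        u[s] = params.utilities.u_disseminated_cancer
    u[_S.SURVEILLANCE] = params.utilities.u_surveillance

    # surveillance cost accrues in the post-diagnosis years and the
    # long-term surveillance state; the diagnosis year itself is treatment
    state_costs = np.zeros(N_INTERNAL)
    for s in _SURV_STATES:
        state_costs[s] = params.costs.c_surveillance_per_year

    # treatment cost charged once on clinical entry; clinically presenting
    # patients incur it with the treatment-receipt probability, while
    # screen-detected ones are treated per the screening-program policy
    tr = params.mortality.treatment_receipt_probability
    tr_scr = 1.0 if params.mortality.screen_detected_always_treated else tr
    entry_costs = np.zeros(N_INTERNAL)
    entry_costs[_S.CLIN_LOCAL_DX] = tr * params.costs.c_treat_local
    entry_costs[_S.CLIN_REGIONAL_DX] = tr * params.costs.c_treat_regional
    entry_costs[_S.CLIN_DISTANT_DX] = tr * params.costs.c_treat_disseminated
    entry_costs[_S.CLIN_LOCAL_SCR] = tr_scr * params.costs.c_treat_local
    entry_costs[_S.CLIN_REGIONAL_SCR] = tr_scr * params.costs.c_treat_regional
    entry_costs[_S.CLIN_DISTANT_SCR] = tr_scr * params.costs.c_treat_disseminated
    return u, state_costs, entry_costs


def _single_pass(
    params: ParameterSet,
    strategy: StrategySpec | None,
    life_table: LifeTable,
    kernels: list[np.ndarray],
    participation: float | None,
) -> dict:
    """One cohort run with a fixed participation policy; returns the raw
    run_markov dict plus colonoscopy counters."""
    econ = params.econ
    start = econ.screening_start_age
    n_cycles = econ.max_age - start
    u, state_costs, entry_costs = _payoff_vectors(params)
    colos = {"n": 0.0, "pdeaths": 0.0}
    stage_state = {
        "localized": _S.CLIN_LOCAL_SCR,
        "regional": _S.CLIN_REGIONAL_SCR,
        "disseminated": _S.CLIN_DISTANT_SCR,
    }

    def screening_op(t: int, x: np.ndarray):
        age = start + t
        if strategy is None or not strategy.tests_at(age):
            return x, 0.0, np.zeros(N_INTERNAL)
        out = apply_screening_cycle(
            x, strategy, age, params, participation=participation
        )
        colos["n"] += out.expected_colonoscopies
        colos["pdeaths"] += out.expected_perforation_deaths
        screen_entries = np.zeros(N_INTERNAL)
        for stage, mass in out.cancers_detected_by_stage.items():
            screen_entries[stage_state[stage]] += mass
        return out.post_screen, out.expected_cost, screen_entries

    res = run_markov(
        init=initial_distribution(params).x,
        kernel=lambda t: kernels[t],
        n_cycles=n_cycles,
        rate=econ.discount_rate,
        utilities=u,
        state_costs=state_costs,
        entry_costs=entry_costs,
        screening=screening_op,
    )
    res["colonoscopies"] = colos["n"]
    res["perforation_deaths"] = colos["pdeaths"]
    return res


_BLEND_KEYS = (
    "trace",
    "entries",
    "screen_cost_by_cycle",
    "discounted_cost",
    "undiscounted_cost",
    "discounted_qalys",
    "undiscounted_qalys",
    "final",
    "colonoscopies",
    "perforation_deaths",
)


def run_cohort(
    params: ParameterSet,
    strategy: StrategySpec | None,
    life_table: LifeTable,
) -> CohortResult:
    """Run one screening strategy (or no screening when ``strategy`` is
    None or offers no tests) over the lifetime horizon.

    Under the default persistent adherence mode a screening strategy is the
    mixture of an always-attending sub-cohort (weight = the modality's
    adherence) and a never-screened sub-cohort; per-event mode draws
    participation independently at every offer.  All reported quantities
    are expectations over the mixture.
    """
    econ = params.econ
    start, end = econ.screening_start_age, econ.max_age
    if life_table.min_age > start:
        raise ParameterError("life table must cover the cohort entry age")
    ages = np.arange(start, end)

    kernels = [
        build_transition_matrix(params, age, life_table).p for age in ages
    ]

    screens = strategy is not None and any(
        strategy.tests_at(a) for a in range(start, econ.screening_stop_age + 1)
    )
    persistent = params.adherence.adherence_mode == "persistent"
    if screens and persistent:
        alpha = getattr(params.adherence, strategy.primary_adherence_key())
        attend = _single_pass(params, strategy, life_table, kernels, 1.0)
        never = _single_pass(params, None, life_table, kernels, None)
        res = {
            k: alpha * attend[k] + (1.0 - alpha) * never[k] for k in _BLEND_KEYS
        }
    else:
        res = _single_pass(
            params, strategy if screens else None, life_table, kernels, None
        )

    # terminal closure: residual living mass at max_age dies of other causes
    final = res["final"].copy()
    living = final.sum() - final[_S.DEAD_CRC] - final[_S.DEAD_OTHER]
    final[_S.DEAD_OTHER] += living
    for s in InternalState:
        if s not in (_S.DEAD_CRC, _S.DEAD_OTHER):
            final[s] = 0.0

    clin_entries = res["entries"][:, list(_CLINICAL)].sum(axis=1)
    living_at_start = 1.0 - res["trace"][:-1, _S.DEAD_CRC] - res["trace"][:-1, _S.DEAD_OTHER]
    with np.errstate(divide="ignore", invalid="ignore"):
        incidence = np.where(
            living_at_start > 0, 1e5 * clin_entries / living_at_start, 0.0
        )

    trace_public = np.vstack(
        [np.apply_along_axis(aggregate_to_public, 1, res["trace"][:-1]),
         aggregate_to_public(final)]
    )

    return CohortResult(
        strategy=strategy.name if strategy is not None else "NO_SCREENING",
        ages=ages,
        trace_public=trace_public,
        discounted_cost=res["discounted_cost"],
        discounted_qalys=res["discounted_qalys"],
        undiscounted_cost=res["undiscounted_cost"],
        undiscounted_qalys=res["undiscounted_qalys"],
        lifetime_crc_deaths=float(final[_S.DEAD_CRC]),
        lifetime_clinical_cases=float(clin_entries.sum()),
        incidence_by_age=incidence,
        expected_colonoscopies=float(res["colonoscopies"]),
        expected_perforation_deaths=float(res["perforation_deaths"]),
    )


def crc_mortality_reduction(result: CohortResult, baseline: CohortResult) -> float:
    """Percent reduction in lifetime cancer deaths vs the baseline run."""
    if baseline.lifetime_crc_deaths <= 0:
        raise ParameterError("baseline has no cancer deaths to compare against")
    return 100.0 * (1.0 - result.lifetime_crc_deaths / baseline.lifetime_crc_deaths)
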