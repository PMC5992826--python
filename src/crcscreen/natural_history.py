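"""Adenoma–carcinoma natural history as an age-specific Markov kernel.

Disease progresses normal mucosa → low-risk polyp (< 1 cm) → high-risk polyp
(> 1 cm) → preclinical cancer (localized → regional → disseminated), with
preclinical cancer surfacing clinically at stage-specific annual rates.
Diagnosed local/regional patients face the annualized 5-year cancer
mortality for five cycles — one diagnosis year plus four aged surveillance
sub-states (a "tunnel") — and, if still alive, settle into long-term
surveillance with no further excess cancer mortality.  Disseminated
patients remain in the clinical disseminated state until death.

Cancer may be diagnosed through two routes: clinical presentation (``_DX``
states) or screen detection (``_SCR`` states).  The routes matter only when
treatment receipt is below 1: presenting patients receive treatment with
the treatment-receipt probability (untreated ones follow the configured
untreated-mortality policy), whereas screen-detected patients are treated
with certainty by default, since a screening program carries its cases into
care.  With full treatment receipt the two routes have identical dynamics.

Background other-cause mortality from the life table competes with every
disease transition: qx is applied first, and the disease kernel acts on the
surviving fraction (multiplicative competing-risk composition).

The public view is the 12-state :class:`HealthState` enumeration; internally
the kernel is built over a 31-state basis that expands the surveillance
tunnels and detection routes.  ``PUBLIC_OF_INTERNAL`` maps one onto the
other.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .life_tables import LifeTable
from .params import MortalityParams, ParameterError, ParameterSet

__all__ = [
    "HealthState",
    "InternalState",
    "PUBLIC_OF_INTERNAL",
    "N_INTERNAL",
    "TransitionMatrix",
    "StateDistribution",
    "annual_from_k_year_prob",
    "stage_mortality_annual",
    "effective_stage_mortality",
    "build_transition_matrix",
    "initial_distribution",
    "aggregate_to_public",
]


class HealthState(enum.IntEnum):
    """The model's 12 public health states; the two dead states are absorbing."""

    NORMAL = 0
    LOW_POLYP = 1
    HIGH_POLYP = 2
    PRECLIN_LOCAL = 3
    PRECLIN_REGIONAL = 4
    PRECLIN_DISTANT = 5
    CLIN_LOCAL = 6
    CLIN_REGIONAL = 7
    CLIN_DISTANT = 8
    SURVEILLANCE = 9
    DEAD_CRC = 10
    DEAD_OTHER = 11


class InternalState(enum.IntEnum):
    """Expanded basis: detection-route clinical states and 5-year tunnels."""

    NORMAL = 0
    LOW_POLYP = 1
    HIGH_POLYP = 2
    PRECLIN_LOCAL = 3
    PRECLIN_REGIONAL = 4
    PRECLIN_DISTANT = 5
    # clinically presenting
    CLIN_LOCAL_DX = 6
    CLIN_REGIONAL_DX = 7
    CLIN_DISTANT_DX = 8
    # screen-detected
    CLIN_LOCAL_SCR = 9
    CLIN_REGIONAL_SCR = 10
    CLIN_DISTANT_SCR = 11
    # post-diagnosis years 2-5, clinically presenting route
    SURV_LOCAL_DX_Y2 = 12
    SURV_LOCAL_DX_Y3 = 13
    SURV_LOCAL_DX_Y4 = 14
    SURV_LOCAL_DX_Y5 = 15
    SURV_REGIONAL_DX_Y2 = 16
    SURV_REGIONAL_DX_Y3 = 17
    SURV_REGIONAL_DX_Y4 = 18
    SURV_REGIONAL_DX_Y5 = 19
    # post-diagnosis years 2-5, screen-detected route
    SURV_LOCAL_SCR_Y2 = 20
    SURV_LOCAL_SCR_Y3 = 21
    SURV_LOCAL_SCR_Y4 = 22
    SURV_LOCAL_SCR_Y5 = 23
    SURV_REGIONAL_SCR_Y2 = 24
    SURV_REGIONAL_SCR_Y3 = 25
    SURV_REGIONAL_SCR_Y4 = 26
    SURV_REGIONAL_SCR_Y5 = 27
    SURVEILLANCE = 28
    DEAD_CRC = 29
    DEAD_OTHER = 30


N_INTERNAL = len(InternalState)

_S = InternalState

CLIN_LOCAL_STATES = (_S.CLIN_LOCAL_DX, _S.CLIN_LOCAL_SCR)
CLIN_REGIONAL_STATES = (_S.CLIN_REGIONAL_DX, _S.CLIN_REGIONAL_SCR)
CLIN_DISTANT_STATES = (_S.CLIN_DISTANT_DX, _S.CLIN_DISTANT_SCR)
CLINICAL_STATES = CLIN_LOCAL_STATES + CLIN_REGIONAL_STATES + CLIN_DISTANT_STATES

_TUNNELS = {
    _S.CLIN_LOCAL_DX: [_S.SURV_LOCAL_DX_Y2, _S.SURV_LOCAL_DX_Y3,
                       _S.SURV_LOCAL_DX_Y4, _S.SURV_LOCAL_DX_Y5],
    _S.CLIN_REGIONAL_DX: [_S.SURV_REGIONAL_DX_Y2, _S.SURV_REGIONAL_DX_Y3,
                          _S.SURV_REGIONAL_DX_Y4, _S.SURV_REGIONAL_DX_Y5],
    _S.CLIN_LOCAL_SCR: [_S.SURV_LOCAL_SCR_Y2, _S.SURV_LOCAL_SCR_Y3,
                        _S.SURV_LOCAL_SCR_Y4, _S.SURV_LOCAL_SCR_Y5],
    _S.CLIN_REGIONAL_SCR: [_S.SURV_REGIONAL_SCR_Y2, _S.SURV_REGIONAL_SCR_Y3,
                           _S.SURV_REGIONAL_SCR_Y4, _S.SURV_REGIONAL_SCR_Y5],
}
TUNNEL_STATES = tuple(s for chain in _TUNNELS.values() for s in chain)

_DEAD = (_S.DEAD_CRC, _S.DEAD_OTHER)


def _public_map() -> dict[InternalState, HealthState]:
    m = {
        _S.NORMAL: HealthState.NORMAL,
        _S.LOW_POLYP: HealthState.LOW_POLYP,
        _S.HIGH_POLYP: HealthState.HIGH_POLYP,
        _S.PRECLIN_LOCAL: HealthState.PRECLIN_LOCAL,
        _S.PRECLIN_REGIONAL: HealthState.PRECLIN_REGIONAL,
        _S.PRECLIN_DISTANT: HealthState.PRECLIN_DISTANT,
        _S.SURVEILLANCE: HealthState.SURVEILLANCE,
        _S.DEAD_CRC: HealthState.DEAD_CRC,
        _S.DEAD_OTHER: HealthState.DEAD_OTHER,
    }
    for s in CLIN_LOCAL_STATES:
        m[s] = HealthState.CLIN_LOCAL
    for s in CLIN_REGIONAL_STATES:
        m[s] = HealthState.CLIN_REGIONAL
    for s in CLIN_DISTANT_STATES:
        m[s] = HealthState.CLIN_DISTANT
    for s in TUNNEL_STATES:
        m[s] = HealthState.SURVEILLANCE
    return m


PUBLIC_OF_INTERNAL = _public_map()


def aggregate_to_public(x: np.ndarray) -> np.ndarray:
    """Collapse an internal-basis occupancy vector onto the 12 public states."""
    out = np.zeros(len(HealthState))
    for s in InternalState:
        out[PUBLIC_OF_INTERNAL[s]] += x[s]
    return out


@dataclass
class StateDistribution:
    """Cohort occupancy over the internal basis; entries >= 0, sum to 1."""

    x: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.x.shape != (N_INTERNAL,):
            raise ParameterError(f"state distribution must have {N_INTERNAL} entries")
        if np.any(self.x < -1e-12):
            raise ParameterError("state distribution has negative occupancy")
        if abs(self.x.sum() - 1.0) > 1e-9:
            raise ParameterError(
                f"state distribution sums to {self.x.sum():.12f}, not 1"
            )

    def public(self) -> np.ndarray:
        return aggregate_to_public(self.x)


@dataclass
class TransitionMatrix:
    """One-cycle kernel over the internal basis at a given age.

    ``p`` includes background mortality; ``conditional`` is the disease
    kernel conditional on surviving other causes (useful for inspecting the
    raw progression probabilities, e.g. low→high polyp 0.036).
    """

    age: int
    p: np.ndarray
    conditional: np.ndarray

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for name, m in (("p", self.p), ("conditional", self.conditional)):
            if m.shape != (N_INTERNAL, N_INTERNAL):
                raise ParameterError(f"transition matrix {name}: wrong shape")
            if np.any((m < -1e-15) | (m > 1 + 1e-12)):
                raise ParameterError(f"transition matrix {name}: entries outside [0,1]")
            rowsum = m.sum(axis=1)
            if np.any(np.abs(rowsum - 1.0) > 1e-12):
                bad = int(np.argmax(np.abs(rowsum - 1.0)))
                raise ParameterError(
                    f"transition matrix {name}: row {InternalState(bad).name} "
                    f"sums to {rowsum[bad]:.15f}"
                )
        for d in _DEAD:
            if self.p[d, d] != 1.0:
                raise ParameterError("dead states must be absorbing")


def annual_from_k_year_prob(p_k: float, k: float) -> float:
    """Annual probability equivalent to a k-year probability under a
    constant hazard: 1 - (1 - p_k)^(1/k)."""
    if not (0.0 <= p_k <= 1.0):
        raise ParameterError(f"k-year probability {p_k!r} outside [0, 1]")
    if k < 1:
        raise ParameterError("k must be >= 1 year")
    return 1.0 - (1.0 - p_k) ** (1.0 / k)


_NEXT_WORSE = {"localized": "regional", "regional": "disseminated"}


def stage_mortality_annual(stage: str, treated: bool, params: MortalityParams) -> float:
    """Annual cancer-death probability for a clinical stage.

    Treated patients: the stage's 5-year mortality annualized.  Untreated
    (``next_worse_stage`` policy): the next-worse stage's 5-year mortality
    annualized; untreated disseminated disease compresses its 5-year
    mortality into 4 years.
    """
    m5 = params.five_year_mortality_treated
    if stage not in m5:
        raise ParameterError(f"unknown cancer stage {stage!r}")
    if treated:
        return annual_from_k_year_prob(m5[stage], 5)
    if params.untreated_policy != "next_worse_stage":
        raise ParameterError(f"unknown untreated policy {params.untreated_policy!r}")
    if stage == "disseminated":
        return annual_from_k_year_prob(m5["disseminated"], 4)
    return annual_from_k_year_prob(m5[_NEXT_WORSE[stage]], 5)


def effective_stage_mortality(stage: str, params: MortalityParams) -> float:
    """Treated/untreated mixture by the treatment-receipt probability."""
    tr = params.treatment_receipt_probability
    m_t = stage_mortality_annual(stage, True, params)
    if tr == 1.0:
        return m_t
    m_u = stage_mortality_annual(stage, False, params)
    return tr * m_t + (1.0 - tr) * m_u


def _route_mortality(stage: str, route: str, params: MortalityParams) -> float:
    """Annual cancer mortality by detection route.

    ``dx`` (clinical presentation): treated/untreated mixture.  ``scr``
    (screen-detected): treated with certainty when the policy says the
    screening program secures treatment, otherwise the same mixture.
    """
    if route == "scr" and getattr(params, "screen_detected_always_treated", True):
        return stage_mortality_annual(stage, True, params)
    return effective_stage_mortality(stage, params)


def _disease_kernel(params: ParameterSet, age: float, treated: bool | None) -> np.ndarray:
    """Disease transitions conditional on surviving other causes this cycle."""
    nh = params.natural_history
    D = np.zeros((N_INTERNAL, N_INTERNAL))

    def stay(s: InternalState) -> None:
        D[s, s] = 1.0 - (D[s].sum() - D[s, s])

    D[_S.NORMAL, _S.LOW_POLYP] = nh.p_normal_to_low(age)
    stay(_S.NORMAL)
    D[_S.LOW_POLYP, _S.HIGH_POLYP] = nh.p_low_to_high
    stay(_S.LOW_POLYP)
    D[_S.HIGH_POLYP, _S.PRECLIN_LOCAL] = nh.p_high_to_preclin_local
    stay(_S.HIGH_POLYP)

    # Two simultaneous exits from a preclinical stage are independent
    # competing events; joint occurrence resolves to clinical presentation
    # (detection preempts further silent progression within the cycle).
    d_loc = nh.p_preclin_local_to_clin
    D[_S.PRECLIN_LOCAL, _S.CLIN_LOCAL_DX] = d_loc
    D[_S.PRECLIN_LOCAL, _S.PRECLIN_REGIONAL] = nh.p_preclin_local_to_regional * (1 - d_loc)
    stay(_S.PRECLIN_LOCAL)
    d_reg = nh.p_preclin_regional_to_clin
    D[_S.PRECLIN_REGIONAL, _S.CLIN_REGIONAL_DX] = d_reg
    D[_S.PRECLIN_REGIONAL, _S.PRECLIN_DISTANT] = nh.p_preclin_regional_to_distant * (1 - d_reg)
    stay(_S.PRECLIN_REGIONAL)
    D[_S.PRECLIN_DISTANT, _S.CLIN_DISTANT_DX] = nh.p_preclin_distant_to_clin
    stay(_S.PRECLIN_DISTANT)

    def mort(stage: str, route: str) -> float:
        if treated is None:
            return _route_mortality(stage, route, params.mortality)
        return stage_mortality_annual(stage, treated, params.mortality)

    # Diagnosis year + 4 tunnel years carry the annualized 5-year mortality;
    # survivors of year 5 enter long-term surveillance.
    for clin, stage, route in (
        (_S.CLIN_LOCAL_DX, "localized", "dx"),
        (_S.CLIN_REGIONAL_DX, "regional", "dx"),
        (_S.CLIN_LOCAL_SCR, "localized", "scr"),
        (_S.CLIN_REGIONAL_SCR, "regional", "scr"),
    ):
        m = mort(stage, route)
        chain = [clin, *_TUNNELS[clin], _S.SURVEILLANCE]
        for src, dst in zip(chain[:-1], chain[1:]):
            D[src, _S.DEAD_CRC] = m
            D[src, dst] = 1.0 - m

    for clin, route in ((_S.CLIN_DISTANT_DX, "dx"), (_S.CLIN_DISTANT_SCR, "scr")):
        m = mort("disseminated", route)
        D[clin, _S.DEAD_CRC] = m
        D[clin, clin] = 1.0 - m

    D[_S.SURVEILLANCE, _S.SURVEILLANCE] = 1.0
    for d in _DEAD:
        D[d, d] = 1.0
    return D


def build_transition_matrix(
    params: ParameterSet,
    age: float,
    life_table: LifeTable,
    treated: bool | None = None,
) -> TransitionMatrix:
    """One-cycle kernel at ``age``: background qx first, disease kernel on
    the surviving fraction.  ``treated=None`` applies the route-dependent
    treatment-receipt mixture to cancer mortality; True/False force one arm.
    """
    if not (life_table.min_age <= age):
        raise ParameterError(f"age {age} below life-table span")
    q = life_table.q(age)
    D = _disease_kernel(params, age, treated)
    P = np.zeros_like(D)
    for s in InternalState:
        if s in _DEAD:
            P[s, s] = 1.0
        else:
            P[s] = (1.0 - q) * D[s]
            P[s, _S.DEAD_OTHER] += q
    return TransitionMatrix(age=int(age), p=P, conditional=D)


def initial_distribution(params: ParameterSet) -> StateDistribution:
    """Cohort at entry (age 50): polyp and preclinical-cancer prevalences,
    remainder normal mucosa."""
    nh = params.natural_history
    start = params.econ.screening_start_age
    x = np.zeros(N_INTERNAL)
    x[_S.LOW_POLYP] = nh.prevalence_low_polyp(start)
    x[_S.HIGH_POLYP] = nh.prevalence_high_polyp(start)
    x[_S.PRECLIN_LOCAL] = nh.prevalence_preclinical_local_at50
    x[_S.PRECLIN_REGIONAL] = nh.prevalence_preclinical_regional_at50
    x[_S.PRECLIN_DISTANT] = nh.prevalence_preclinical_distant_at50
    rest = 1.0 - x.sum()
    if rest < 0:
        raise ParameterError("initial prevalences sum to more than 1")
    x[_S.NORMAL] = rest
    return StateDistribution(x)
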