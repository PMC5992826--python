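"""Screening strategies and their per-cycle effect on the cohort.

Three programs are compared against no screening: annual FOBT, annual FOBT
plus flexible sigmoidoscopy every 5 years, and colonoscopy every 10 years,
all offered from age 50 through 75.  Positive FOBT/sigmoidoscopy results
lead to confirmatory colonoscopy; polyps are removed only at colonoscopy
(returning the individual to normal mucosa), and screen-detected preclinical
cancers are diagnosed at their current stage (a stage freeze — the benefit
mechanism of early detection).  Colonoscopy carries a perforation risk with
its own treatment cost and case fatality.

Screening is applied at cycle start, before that cycle's natural-history
transitions, so it detects prevalent lesions.  Participation with primary
offers follows the adherence mode configured on the parameter set (a
persistent attender/never-attender split by default; see
``AdherenceParams``); the cohort engine realizes the persistent mode by
blending an always-attending sub-cohort with a never-screened one, so the
per-cycle operator here simply takes the participation probability that
applies to the sub-cohort it is acting on.  All quantities are cohort
expectations: the operator maps an occupancy vector to a post-screening
occupancy vector plus expected costs, colonoscopies, perforations and
detected cancers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .natural_history import InternalState, N_INTERNAL
from .params import ParameterError, ParameterSet

__all__ = [
    "FOBT",
    "SIGMOIDOSCOPY",
    "COLONOSCOPY",
    "StrategySpec",
    "ScreeningCycleOutcome",
    "builtin_strategies",
    "test_positivity",
    "colonoscopy_resolution",
    "apply_screening_cycle",
]

FOBT = "FOBT"
SIGMOIDOSCOPY = "SIGMOIDOSCOPY"
COLONOSCOPY = "COLONOSCOPY"
_KNOWN_TESTS = (FOBT, SIGMOIDOSCOPY, COLONOSCOPY)

# States a screening test can be offered to (undiagnosed, alive).
_S = InternalState
_SCREENABLE = (
    _S.NORMAL,
    _S.LOW_POLYP,
    _S.HIGH_POLYP,
    _S.PRECLIN_LOCAL,
    _S.PRECLIN_REGIONAL,
    _S.PRECLIN_DISTANT,
)
_LESION_CLASS = {
    _S.LOW_POLYP: "low_polyp",
    _S.HIGH_POLYP: "high_polyp",
    _S.PRECLIN_LOCAL: "cancer",
    _S.PRECLIN_REGIONAL: "cancer",
    _S.PRECLIN_DISTANT: "cancer",
}
# screen-detected cancers enter the screen-detected clinical route at
# their current stage (early detection is a stage freeze)
_CLINICAL_OF_PRECLIN = {
    _S.PRECLIN_LOCAL: (_S.CLIN_LOCAL_SCR, "localized"),
    _S.PRECLIN_REGIONAL: (_S.CLIN_REGIONAL_SCR, "regional"),
    _S.PRECLIN_DISTANT: (_S.CLIN_DISTANT_SCR, "disseminated"),
}


@dataclass
class StrategySpec:
    """A screening protocol: which tests are offered at which ages.

    Intervals are in years; ``None`` disables the modality.  In years where
    FOBT and sigmoidoscopy coincide they form a combined offer with a single
    participation draw; either test positive triggers confirmatory
    colonoscopy.
    """

    name: str
    fobt_interval: int | None = None
    sigmo_interval: int | None = None
    colo_interval: int | None = None
    start_age: int = 50
    stop_age: int = 75
    adherence_key: str | None = None  # derived from offered tests when None

    def primary_adherence_key(self) -> str:
        """AdherenceParams attribute governing participation with this
        program's primary offers."""
        if self.adherence_key is not None:
            return self.adherence_key
        if self.colo_interval is not None:
            return "adherence_colonoscopy"
        if self.sigmo_interval is not None:
            return "adherence_sigmo_fobt"
        return "adherence_fobt"

    def validate(self, econ_start: int, econ_stop: int) -> "StrategySpec":
        if self.start_age < econ_start or self.stop_age > econ_stop:
            raise ParameterError(
                f"strategy {self.name}: tests offered outside the screening "
                f"window [{econ_start}, {econ_stop}]"
            )
        return self

    def tests_at(self, age: float) -> set[str]:
        """Set of tests offered at integer ``age`` (empty off-schedule)."""
        a = int(age)
        if a < self.start_age or a > self.stop_age:
            return set()
        offered = set()
        for test, interval in (
            (FOBT, self.fobt_interval),
            (SIGMOIDOSCOPY, self.sigmo_interval),
            (COLONOSCOPY, self.colo_interval),
        ):
            if interval is not None and (a - self.start_age) % interval == 0:
                offered.add(test)
        return offered

    @classmethod
    def from_config(cls, data: dict) -> "StrategySpec":
        known = {"name", "fobt_interval", "sigmo_interval", "colo_interval",
                 "start_age", "stop_age"}
        bad = set(data) - known
        if bad:
            raise ParameterError(f"strategy config: unknown keys {sorted(bad)}")
        if "name" not in data:
            raise ParameterError("strategy config: missing name")
        return cls(**data)


NO_SCREENING = "NO_SCREENING"
FOBT_ANNUAL = "FOBT_ANNUAL"
SIGMO_FOBT = "SIGMO_FOBT"
COLO_10 = "COLO_10"


def builtin_strategies(econ) -> list[StrategySpec]:
    """The four compared programs over the configured screening window."""
    start, stop = econ.screening_start_age, econ.screening_stop_age
    specs = [
        StrategySpec(NO_SCREENING, start_age=start, stop_age=stop),
        StrategySpec(FOBT_ANNUAL, fobt_interval=1, start_age=start, stop_age=stop),
        StrategySpec(
            SIGMO_FOBT, fobt_interval=1, sigmo_interval=5, start_age=start, stop_age=stop
        ),
        StrategySpec(COLO_10, colo_interval=10, start_age=start, stop_age=stop),
    ]
    return [s.validate(start, stop) for s in specs]


def test_positivity(test: str, state: InternalState, tests) -> float:
    """Probability the test reads positive for an individual in ``state``.

    FOBT: lesion-class sensitivity, 1 - specificity on normal mucosa.
    Colonoscopy: endoscopic sensitivities, perfect specificity.
    Sigmoidoscopy: colonoscopy sensitivities scaled by the within-reach
    factor (1 - probability the neoplasm is proximal to the scope).
    """
    if test not in _KNOWN_TESTS:
        raise ParameterError(f"unknown test {test!r}")
    state = InternalState(state)
    if state not in _SCREENABLE:
        raise ParameterError(f"test offered to unscreenable state {state.name}")
    if state is _S.NORMAL:
        if test == FOBT:
            return 1.0 - tests.fobt_specificity
        return 1.0 - tests.endo_specificity
    lesion = _LESION_CLASS[state]
    if test == FOBT:
        sens = {
            "low_polyp": tests.fobt_sensitivity_low_polyp,
            "high_polyp": tests.fobt_sensitivity_high_polyp,
            "cancer": tests.fobt_sensitivity_cancer,
        }[lesion]
        return sens
    sens = {
        "low_polyp": tests.endo_sensitivity_low_polyp,
        "high_polyp": tests.endo_sensitivity_high_polyp,
        "cancer": tests.endo_sensitivity_cancer,
    }[lesion]
    if test == SIGMOIDOSCOPY:
        return sens * (1.0 - tests.p_proximal_missed_by_sigmoidoscopy)
    return sens


@dataclass
class ColonoscopyResolution:
    """Expected outcome of performing one colonoscopy on a given state."""

    outcomes: dict[InternalState, float]  # destination state -> probability
    detected_cancer_stage: str | None
    p_detected: float
    p_perforation: float
    p_perforation_death: float
    expected_cost: float


def colonoscopy_resolution(
    state: InternalState, params: ParameterSet
) -> ColonoscopyResolution:
    """Resolve one colonoscopy: polyp removal back to normal mucosa,
    preclinical cancer diagnosed at its current stage, perforation risk and
    costs.  Perforation deaths preempt the endoscopic finding."""
    state = InternalState(state)
    if state not in _SCREENABLE:
        raise ParameterError(f"colonoscopy on unscreenable state {state.name}")
    t = params.tests
    p_perf = t.p_perforation_per_colonoscopy
    p_pdeath = p_perf * t.p_death_given_perforation
    detected = test_positivity(COLONOSCOPY, state, t)
    stage = None
    if state in (_S.LOW_POLYP, _S.HIGH_POLYP):
        target = _S.NORMAL
    elif state in _CLINICAL_OF_PRECLIN:
        target, stage = _CLINICAL_OF_PRECLIN[state]
    else:  # NORMAL with perfect specificity: nothing to find
        target = state
        detected = 0.0
    live = 1.0 - p_pdeath
    outcomes: dict[InternalState, float] = {_S.DEAD_OTHER: p_pdeath}
    outcomes[target] = outcomes.get(target, 0.0) + live * detected
    outcomes[state] = outcomes.get(state, 0.0) + live * (1.0 - detected)
    cost = params.costs.c_colonoscopy + p_perf * params.costs.c_perforation_treatment
    return ColonoscopyResolution(
        outcomes=outcomes,
        detected_cancer_stage=stage,
        p_detected=live * detected,
        p_perforation=p_perf,
        p_perforation_death=p_pdeath,
        expected_cost=cost,
    )


@dataclass
class ScreeningCycleOutcome:
    """Cohort expectations from one screening round (per cohort member)."""

    post_screen: np.ndarray
    expected_cost: float
    expected_colonoscopies: float
    expected_perforations: float
    expected_perforation_deaths: float
    cancers_detected_by_stage: dict[str, float] = field(default_factory=dict)

    @property
    def total_cancers_detected(self) -> float:
        return sum(self.cancers_detected_by_stage.values())


def _participation_and_positivity(
    offered: set[str], state: InternalState, params: ParameterSet
) -> tuple[float, float, float, bool]:
    """Return (participation, primary-test cost per attender, probability the
    visit leads to a colonoscopy, colonoscopy_is_primary).

    Primary colonoscopy carries no separate offer cost: the colonoscopy
    itself is costed in the resolution step."""
    adh = params.adherence
    costs = params.costs
    if offered == {COLONOSCOPY}:
        return adh.adherence_colonoscopy, 0.0, 1.0, True
    if offered == {FOBT}:
        p_pos = test_positivity(FOBT, state, params.tests)
        return (
            adh.adherence_fobt,
            costs.c_fobt,
            p_pos * adh.adherence_confirmatory_colonoscopy,
            False,
        )
    if offered == {FOBT, SIGMOIDOSCOPY}:
        # combined offer: one participation draw, positive if either test is
        p_f = test_positivity(FOBT, state, params.tests)
        p_s = test_positivity(SIGMOIDOSCOPY, state, params.tests)
        p_pos = 1.0 - (1.0 - p_f) * (1.0 - p_s)
        return (
            adh.adherence_sigmo_fobt,
            costs.c_fobt + costs.c_sigmoidoscopy,
            p_pos * adh.adherence_confirmatory_colonoscopy,
            False,
        )
    raise ParameterError(f"unsupported test combination {sorted(offered)}")


def apply_screening_cycle(
    dist: np.ndarray,
    strategy: StrategySpec,
    age: float,
    params: ParameterSet,
    participation: float | None = None,
) -> ScreeningCycleOutcome:
    """Apply one screening round to the cohort occupancy vector.

    Only undiagnosed living states are screened; clinical, surveillance and
    dead states pass through.  Probability mass is conserved except for
    perforation deaths, which move to death from other causes.

    ``participation`` overrides the per-offer participation probability
    (the cohort engine passes 1.0 for the attender sub-cohort in the
    persistent adherence mode; ``None`` uses the per-event adherence
    parameters).
    """
    x = np.asarray(dist, dtype=float)
    if x.shape != (N_INTERNAL,):
        raise ParameterError("screening: distribution has wrong length")
    offered = strategy.tests_at(age)
    if offered and not (
        params.econ.screening_start_age <= int(age) <= params.econ.screening_stop_age
    ):
        raise ParameterError(
            f"strategy {strategy.name} offers tests at age {age}, outside the window"
        )
    out = x.copy()
    cost = 0.0
    colos = 0.0
    perfs = 0.0
    perf_deaths = 0.0
    detected: dict[str, float] = {}
    if not offered:
        return ScreeningCycleOutcome(out, 0.0, 0.0, 0.0, 0.0, {})

    for state in _SCREENABLE:
        mass = x[state]
        if mass == 0.0:
            continue
        partic, primary_cost, p_colo, _ = _participation_and_positivity(
            offered, state, params
        )
        if participation is not None:
            partic = participation
        attending = mass * partic
        cost += attending * primary_cost
        colo_mass = attending * p_colo
        if colo_mass == 0.0:
            continue
        res = colonoscopy_resolution(state, params)
        cost += colo_mass * res.expected_cost
        colos += colo_mass
        perfs += colo_mass * res.p_perforation
        perf_deaths += colo_mass * res.p_perforation_death
        out[state] -= colo_mass
        for target, p in res.outcomes.items():
            out[target] += colo_mass * p
        if res.detected_cancer_stage is not None:
            detected[res.detected_cancer_stage] = (
                detected.get(res.detected_cancer_stage, 0.0)
                + colo_mass * res.p_detected
            )
    if np.any(out < -1e-12):
        raise ParameterError("screening produced negative occupancy")
    return ScreeningCycleOutcome(
        post_screen=out,
        expected_cost=cost,
        expected_colonoscopies=colos,
        expected_perforations=perfs,
        expected_perforation_deaths=perf_deaths,
        cancers_detected_by_stage=detected,
    )
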