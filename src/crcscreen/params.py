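"""Model parameters: definition, validation, base case, and (de)serialization.

The base case bundles every quantity of the published parameter table for
the Ukrainian colorectal-cancer screening model: natural-history prevalences
and yearly transition probabilities, stage-specific 5-year cancer mortality,
screening adherence, test characteristics, colonoscopy complications, QALY
weights, 2012-US$ costs, and economic settings (3 %/year discounting,
per-capita GDP 3900 US$, screening window ages 50-75).

Parameters are addressed by dotted paths (``costs.c_colonoscopy``,
``adherence.adherence_colonoscopy``); the ``ranges`` map on
:class:`ParameterSet` holds the one-way sensitivity interval for every
parameter the source table gives a range for.  Age-indexed quantities are
:class:`AgeSchedule` anchors interpolated linearly; their sensitivity range
is expressed as a multiplicative-factor interval applied to all anchors.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = [
    "AgeSchedule",
    "NaturalHistoryParams",
    "MortalityParams",
    "ScreeningTestParams",
    "AdherenceParams",
    "UtilityParams",
    "CostParams",
    "EconParams",
    "ParameterSet",
    "ParameterError",
    "base_case_parameter_set",
    "load_parameter_set",
    "save_parameter_set",
    "interpolate_schedule",
    "get_param",
    "set_param",
]


class ParameterError(ValueError):
    """Raised when a parameter value or config file violates the schema."""


def _check_prob(value: float, key: str) -> None:
    if not (0.0 <= value <= 1.0):
        raise ParameterError(f"{key}: probability {value!r} outside [0, 1]")


def _check_nonneg(value: float, key: str) -> None:
    if value < 0:
        raise ParameterError(f"{key}: value {value!r} must be nonnegative")


@dataclass
class AgeSchedule:
    """Age-anchored probability/prevalence, linearly interpolated.

    ``anchors`` is a list of ``(age, value)`` pairs with strictly increasing
    ages; outside the anchored span the boundary value is held constant.
    """

    anchors: list[tuple[float, float]]

    def validate(self, key: str = "schedule") -> None:
        if not self.anchors:
            raise ParameterError(f"{key}: schedule needs at least one anchor")
        ages = [a for a, _ in self.anchors]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ParameterError(f"{key}: anchor ages must be strictly increasing")
        for age, v in self.anchors:
            _check_prob(v, f"{key}@{age}")

    def __call__(self, age: float) -> float:
        return interpolate_schedule(self, age)

    def scaled(self, factor: float) -> "AgeSchedule":
        """Schedule with every anchor value multiplied by ``factor``."""
        return AgeSchedule([(a, v * factor) for a, v in self.anchors])


def interpolate_schedule(schedule: AgeSchedule, age: float) -> float:
    """Piecewise-linear interpolation between anchors, constant outside."""
    if not schedule.anchors:
        raise ParameterError("cannot interpolate an empty schedule")
    ages = np.array([a for a, _ in schedule.anchors], dtype=float)
    vals = np.array([v for _, v in schedule.anchors], dtype=float)
    return float(np.interp(age, ages, vals))


@dataclass
class NaturalHistoryParams:
    prevalence_low_polyp: AgeSchedule
    prevalence_high_polyp: AgeSchedule
    prevalence_preclinical_local_at50: float
    prevalence_preclinical_regional_at50: float
    prevalence_preclinical_distant_at50: float
    p_normal_to_low: AgeSchedule
    p_low_to_high: float
    p_high_to_preclin_local: float
    p_preclin_local_to_regional: float
    p_preclin_regional_to_distant: float
    p_preclin_local_to_clin: float
    p_preclin_regional_to_clin: float
    p_preclin_distant_to_clin: float

    def validate(self) -> None:
        prefix = "natural_history"
        for name in (
            "prevalence_low_polyp",
            "prevalence_high_polyp",
            "p_normal_to_low",
        ):
            getattr(self, name).validate(f"{prefix}.{name}")
        for name in (
            "prevalence_preclinical_local_at50",
            "prevalence_preclinical_regional_at50",
            "prevalence_preclinical_distant_at50",
            "p_low_to_high",
            "p_high_to_preclin_local",
            "p_preclin_local_to_regional",
            "p_preclin_regional_to_distant",
            "p_preclin_local_to_clin",
            "p_preclin_regional_to_clin",
            "p_preclin_distant_to_clin",
        ):
            _check_prob(getattr(self, name), f"{prefix}.{name}")


STAGES = ("localized", "regional", "disseminated")


@dataclass
class MortalityParams:
    """Stage-specific cancer mortality and treatment receipt.

    ``five_year_mortality_treated`` are 5-year death probabilities with
    treatment (SEER-based).  ``treatment_receipt_probability`` is the chance a
    diagnosed patient actually receives treatment (1.0 in the base case; the
    decreased-adherence scenario lowers it to 0.75).  Untreated patients
    follow ``untreated_policy``; the default ``next_worse_stage`` assigns
    them the annualized mortality of one stage worse (disseminated untreated:
    the 5-year 0.92 compressed into 4 years).

    ``screen_detected_always_treated`` keeps screen-detected cancers in the
    treated arm regardless of the receipt probability — a screening program
    carries its cases into care — so reduced treatment receipt acts on
    clinically presenting disease.
    """

    five_year_mortality_treated: dict[str, float]
    untreated_policy: str = "next_worse_stage"
    treatment_receipt_probability: float = 1.0
    screen_detected_always_treated: bool = True

    def validate(self) -> None:
        for stage in STAGES:
            if stage not in self.five_year_mortality_treated:
                raise ParameterError(f"mortality: missing stage {stage!r}")
            _check_prob(
                self.five_year_mortality_treated[stage],
                f"mortality.five_year_mortality_treated.{stage}",
            )
        if self.untreated_policy not in ("next_worse_stage",):
            raise ParameterError(
                f"mortality.untreated_policy: unknown policy {self.untreated_policy!r}"
            )
        _check_prob(
            self.treatment_receipt_probability,
            "mortality.treatment_receipt_probability",
        )


@dataclass
class ScreeningTestParams:
    fobt_sensitivity_low_polyp: float
    fobt_sensitivity_high_polyp: float
    fobt_sensitivity_cancer: float
    fobt_specificity: float
    endo_sensitivity_low_polyp: float
    endo_sensitivity_high_polyp: float
    endo_sensitivity_cancer: float
    endo_specificity: float
    p_proximal_missed_by_sigmoidoscopy: float
    p_perforation_per_colonoscopy: float
    p_death_given_perforation: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_prob(getattr(self, f.name), f"tests.{f.name}")


@dataclass
class AdherenceParams:
    """Participation with screening offers.

    ``adherence_mode`` sets how the per-modality probabilities act on the
    cohort: ``persistent`` (default) splits the population once into
    lifelong attenders and never-attenders — the structure behind published
    screening-program evaluations, where a fixed fraction of invitees is
    simply never reached; ``per_event`` draws participation independently
    at every offer.  Confirmatory colonoscopy after a positive screen is
    always a per-event probability.
    """

    adherence_fobt: float
    adherence_sigmo_fobt: float
    adherence_colonoscopy: float
    adherence_confirmatory_colonoscopy: float
    adherence_mode: str = "persistent"

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            if f.name == "adherence_mode":
                continue
            _check_prob(getattr(self, f.name), f"adherence.{f.name}")
        if self.adherence_mode not in ("persistent", "per_event"):
            raise ParameterError(
                f"adherence.adherence_mode: unknown mode {self.adherence_mode!r}"
            )


@dataclass
class UtilityParams:
    """Annual utility weights. Healthy, polyp and preclinical states carry
    the healthy-state weight; the surveillance weight applies after the
    5-year post-diagnosis window (no published value; default 0.9)."""

    u_healthy_and_polyp_states: float = 1.0
    u_local_regional_cancer: float = 0.7
    u_disseminated_cancer: float = 0.25
    u_surveillance: float = 0.9

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_prob(getattr(self, f.name), f"utilities.{f.name}")


@dataclass
class CostParams:
    """All costs in 2012 US$."""

    c_colonoscopy: float
    c_fobt: float
    c_sigmoidoscopy: float
    c_perforation_treatment: float
    c_treat_local: float
    c_treat_regional: float
    c_treat_disseminated: float
    c_surveillance_per_year: float

    def validate(self) -> None:
        for f in dataclasses.fields(self):
            _check_nonneg(getattr(self, f.name), f"costs.{f.name}")


@dataclass
class EconParams:
    discount_rate: float = 0.03
    gdp_per_capita: float = 3900.0
    screening_start_age: int = 50
    screening_stop_age: int = 75
    max_age: int = 100

    def validate(self) -> None:
        if self.discount_rate < 0:
            raise ParameterError("econ.discount_rate: must be >= 0")
        if self.gdp_per_capita <= 0:
            raise ParameterError("econ.gdp_per_capita: must be > 0")
        if not (self.screening_start_age < self.screening_stop_age <= self.max_age):
            raise ParameterError(
                "econ: require screening_start_age < screening_stop_age <= max_age"
            )


@dataclass
class ParameterSet:
    natural_history: NaturalHistoryParams
    mortality: MortalityParams
    tests: ScreeningTestParams
    adherence: AdherenceParams
    utilities: UtilityParams
    costs: CostParams
    econ: EconParams
    ranges: dict[str, tuple[float, float]] = field(default_factory=dict)

    def validate(self) -> "ParameterSet":
        self.natural_history.validate()
        self.mortality.validate()
        self.tests.validate()
        self.adherence.validate()
        self.utilities.validate()
        self.costs.validate()
        self.econ.validate()
        for key, (lo, hi) in self.ranges.items():
            if lo > hi:
                raise ParameterError(f"ranges.{key}: low {lo} exceeds high {hi}")
        return self

    def copy(self) -> "ParameterSet":
        return copy.deepcopy(self)

    # -- dict/YAML round trip ------------------------------------------------

    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, AgeSchedule):
                return {"anchors": [[float(a), float(v)] for a, v in obj.anchors]}
            if dataclasses.is_dataclass(obj):
                return {
                    f.name: conv(getattr(obj, f.name)) for f in dataclasses.fields(obj)
                }
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, tuple):
                return [conv(v) for v in obj]
            return obj

        return conv(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ParameterSet":
        def sched(d, key):
            if isinstance(d, AgeSchedule):
                return d
            try:
                return AgeSchedule([(float(a), float(v)) for a, v in d["anchors"]])
            except (KeyError, TypeError, ValueError) as exc:
                raise ParameterError(f"{key}: malformed age schedule: {exc}") from exc

        def build(klass, d, prefix):
            kwargs = {}
            names = {f.name: f for f in dataclasses.fields(klass)}
            for key in d:
                if key not in names:
                    raise ParameterError(f"unknown key {prefix}.{key}")
            for name, f in names.items():
                if name not in d:
                    if f.default is not dataclasses.MISSING:
                        kwargs[name] = f.default
                        continue
                    if f.default_factory is not dataclasses.MISSING:
                        kwargs[name] = f.default_factory()
                        continue
                    raise ParameterError(f"missing key {prefix}.{name}")
                val = d[name]
                if f.type == "AgeSchedule":
                    kwargs[name] = sched(val, f"{prefix}.{name}")
                else:
                    kwargs[name] = val
            return klass(**kwargs)

        sections = {
            "natural_history": NaturalHistoryParams,
            "mortality": MortalityParams,
            "tests": ScreeningTestParams,
            "adherence": AdherenceParams,
            "utilities": UtilityParams,
            "costs": CostParams,
            "econ": EconParams,
        }
        for key in data:
            if key not in sections and key != "ranges":
                raise ParameterError(f"unknown top-level key {key!r}")
        kwargs = {}
        for name, klass in sections.items():
            if name not in data:
                raise ParameterError(f"missing section {name!r}")
            kwargs[name] = build(klass, data[name], name)
        ranges = {
            k: (float(lo), float(hi))
            for k, (lo, hi) in data.get("ranges", {}).items()
        }
        return cls(ranges=ranges, **kwargs).validate()


# ---------------------------------------------------------------------------
# Base case
# ---------------------------------------------------------------------------

def base_case_parameter_set() -> ParameterSet:
    """The published base case, complete with sensitivity ranges.

    Age-schedule ranges are stored as multiplicative-factor intervals: the
    intersection over anchors of (anchor low / base, anchor high / base), so
    any factor in the interval keeps every anchor inside its printed range.
    The normal-mucosa onset schedule's printed range is itself "± 10 %".
    """
    nh = NaturalHistoryParams(
        prevalence_low_polyp=AgeSchedule([(50, 0.2), (60, 0.4), (70, 0.5)]),
        prevalence_high_polyp=AgeSchedule(
            [(50, 0.05), (60, 0.09), (70, 0.16), (80, 0.21)]
        ),
        prevalence_preclinical_local_at50=0.0024,
        prevalence_preclinical_regional_at50=0.0012,
        prevalence_preclinical_distant_at50=0.0004,
        p_normal_to_low=AgeSchedule(
            [(50, 0.00836), (55, 0.0099), (60, 0.01156), (65, 0.0133), (70, 0.01521)]
        ),
        p_low_to_high=0.036,
        p_high_to_preclin_local=0.042,
        p_preclin_local_to_regional=0.17,
        p_preclin_regional_to_distant=0.10,
        p_preclin_local_to_clin=0.17,
        p_preclin_regional_to_clin=0.21,
        p_preclin_distant_to_clin=1.0,
    )
    mortality = MortalityParams(
        five_year_mortality_treated={
            "localized": 0.1,
            "regional": 0.35,
            "disseminated": 0.92,
        },
    )
    tests = ScreeningTestParams(
        fobt_sensitivity_low_polyp=0.03,
        fobt_sensitivity_high_polyp=0.34,
        fobt_sensitivity_cancer=0.72,
        fobt_specificity=0.91,
        endo_sensitivity_low_polyp=0.92,
        endo_sensitivity_high_polyp=0.97,
        endo_sensitivity_cancer=0.93,
        endo_specificity=1.0,
        p_proximal_missed_by_sigmoidoscopy=0.21,
        p_perforation_per_colonoscopy=0.0008,
        p_death_given_perforation=0.012,
    )
    adherence = AdherenceParams(
        adherence_fobt=0.75,
        adherence_sigmo_fobt=0.75,
        adherence_colonoscopy=0.8,
        adherence_confirmatory_colonoscopy=0.84,
    )
    utilities = UtilityParams()
    costs = CostParams(
        c_colonoscopy=100.0,
        c_fobt=8.0,
        c_sigmoidoscopy=20.0,
        c_perforation_treatment=500.0,
        c_treat_local=500.0,
        c_treat_regional=9000.0,
        c_treat_disseminated=20000.0,
        c_surveillance_per_year=200.0,
    )
    econ = EconParams()
    ranges: dict[str, tuple[float, float]] = {
        # age-schedule factor intervals (see docstring)
        "natural_history.prevalence_low_polyp": (0.90, 1.10),
        "natural_history.prevalence_high_polyp": (0.952, 1.048),
        "natural_history.p_normal_to_low": (0.90, 1.10),
        "natural_history.prevalence_preclinical_local_at50": (0.002, 0.0026),
        "natural_history.prevalence_preclinical_regional_at50": (0.0008, 0.0014),
        "natural_history.prevalence_preclinical_distant_at50": (0.0003, 0.0005),
        "natural_history.p_low_to_high": (0.025, 0.047),
        "natural_history.p_high_to_preclin_local": (0.03, 0.051),
        "natural_history.p_preclin_local_to_regional": (0.12, 0.22),
        "natural_history.p_preclin_regional_to_distant": (0.05, 0.15),
        "natural_history.p_preclin_local_to_clin": (0.12, 0.23),
        "natural_history.p_preclin_regional_to_clin": (0.16, 0.26),
        "adherence.adherence_fobt": (0.4, 0.8),
        "adherence.adherence_sigmo_fobt": (0.4, 0.8),
        "adherence.adherence_colonoscopy": (0.4, 0.8),
        "adherence.adherence_confirmatory_colonoscopy": (0.4, 0.9),
        "tests.fobt_sensitivity_low_polyp": (0.01, 0.1),
        "tests.fobt_sensitivity_high_polyp": (0.2, 0.5),
        "tests.fobt_sensitivity_cancer": (0.5, 0.85),
        "tests.fobt_specificity": (0.7, 0.96),
        "tests.endo_sensitivity_low_polyp": (0.75, 0.95),
        "tests.endo_sensitivity_high_polyp": (0.75, 0.97),
        "tests.endo_sensitivity_cancer": (0.75, 0.95),
        "tests.p_proximal_missed_by_sigmoidoscopy": (0.11, 0.31),
        "tests.p_death_given_perforation": (0.01, 0.02),
        "tests.p_perforation_per_colonoscopy": (0.0006, 0.005),
        "utilities.u_local_regional_cancer": (0.52, 0.9),
        "utilities.u_disseminated_cancer": (0.15, 0.35),
        "costs.c_colonoscopy": (30.0, 300.0),
        "costs.c_fobt": (5.0, 20.0),
        "costs.c_sigmoidoscopy": (10.0, 100.0),
        "costs.c_perforation_treatment": (200.0, 1000.0),
        "costs.c_treat_local": (200.0, 1500.0),
        "costs.c_treat_regional": (500.0, 15000.0),
        "costs.c_treat_disseminated": (5000.0, 25000.0),
        "costs.c_surveillance_per_year": (100.0, 500.0),
    }
    return ParameterSet(
        natural_history=nh,
        mortality=mortality,
        tests=tests,
        adherence=adherence,
        utilities=utilities,
        costs=costs,
        econ=econ,
        ranges=ranges,
    ).validate()


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def _deep_merge(base: dict, override: dict, prefix: str = "") -> dict:
    out = dict(base)
    for key, val in override.items():
        path = f"{prefix}{key}"
        if key not in base:
            raise ParameterError(f"unknown key {path!r} in override")
        if isinstance(base[key], dict) and isinstance(val, dict):
            out[key] = _deep_merge(base[key], val, prefix=f"{path}.")
        else:
            out[key] = val
    return out


def load_parameter_set(path: str | Path | None = None) -> ParameterSet:
    """Base-case parameters with optional YAML overrides.

    The file mirrors :meth:`ParameterSet.to_dict`; any omitted key keeps its
    base-case value.  Unknown keys and out-of-bounds values raise
    :class:`ParameterError` naming the offending key.
    """
    base = base_case_parameter_set().to_dict()
    if path is not None:
        with open(path) as fh:
            override = yaml.safe_load(fh) or {}
        if not isinstance(override, dict):
            raise ParameterError("config file must contain a mapping")
        base = _deep_merge(base, override)
    return ParameterSet.from_dict(base)


def save_parameter_set(params: ParameterSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Dotted-path access (sensitivity machinery)
# ---------------------------------------------------------------------------

def get_param(params: ParameterSet, param_id: str):
    """Resolve a dotted parameter id. AgeSchedule-valued ids return the
    schedule object (their sweep semantics is multiplicative, see set_param)."""
    obj = params
    for part in param_id.split("."):
        if isinstance(obj, dict):
            try:
                obj = obj[part]
            except KeyError as exc:
                raise ParameterError(f"unknown parameter id {param_id!r}") from exc
        else:
            if not hasattr(obj, part):
                raise ParameterError(f"unknown parameter id {param_id!r}")
            obj = getattr(obj, part)
    return obj


def set_param(params: ParameterSet, param_id: str, value: float) -> ParameterSet:
    """Return a copy with ``param_id`` set to ``value`` (validated).

    For scalar parameters ``value`` is the new value; for age schedules it is
    a multiplicative factor applied to every anchor of the *given* set's
    schedule.
    """
    new = params.copy()
    parts = param_id.split(".")
    obj = new
    for part in parts[:-1]:
        if isinstance(obj, dict):
            obj = obj[part]
        else:
            if not hasattr(obj, part):
                raise ParameterError(f"unknown parameter id {param_id!r}")
            obj = getattr(obj, part)
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise ParameterError(f"unknown parameter id {param_id!r}")
        obj[leaf] = float(value)
    else:
        if not hasattr(obj, leaf):
            raise ParameterError(f"unknown parameter id {param_id!r}")
        current = getattr(obj, leaf)
        if isinstance(current, AgeSchedule):
            setattr(obj, leaf, current.scaled(float(value)))
        else:
            setattr(obj, leaf, float(value))
    return new.validate()
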