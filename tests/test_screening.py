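"""Screening strategies, test positivity, cascades, cohort operator."""

import numpy as np
import pytest

from crcscreen.natural_history import (
    HealthState,
    InternalState as S,
    N_INTERNAL,
    initial_distribution,
)
from crcscreen.params import ParameterError
from crcscreen.screening import (
    COLONOSCOPY,
    FOBT,
    SIGMOIDOSCOPY,
    StrategySpec,
    apply_screening_cycle,
    builtin_strategies,
    colonoscopy_resolution,
)
from crcscreen.screening import test_positivity as positivity
from crcscreen.cohort import run_cohort


def all_normal():
    x = np.zeros(N_INTERNAL)
    x[S.NORMAL] = 1.0
    return x


class TestStrategySchedules:
    def test_colonoscopy_every_ten_years(self, base_params):
        colo = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "COLO_10"
        )
        offered = [a for a in range(50, 76) if colo.tests_at(a)]
        assert offered == [50, 60, 70]

    def test_sigmoidoscopy_every_five_years(self, base_params):
        sf = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "SIGMO_FOBT"
        )
        sig_years = [a for a in range(50, 76) if SIGMOIDOSCOPY in sf.tests_at(a)]
        assert sig_years == [50, 55, 60, 65, 70, 75]
        fobt_years = [a for a in range(50, 76) if FOBT in sf.tests_at(a)]
        assert fobt_years == list(range(50, 76))

    def test_no_screening_offers_nothing(self, base_params):
        ns = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "NO_SCREENING"
        )
        assert all(not ns.tests_at(a) for a in range(40, 110))

    def test_no_tests_outside_window(self, base_params):
        for strat in builtin_strategies(base_params.econ):
            assert not strat.tests_at(49)
            assert not strat.tests_at(76)

    def test_window_violation_rejected(self, base_params):
        bad = StrategySpec("EARLY", fobt_interval=1, start_age=40, stop_age=75)
        with pytest.raises(ParameterError, match="outside the screening"):
            bad.validate(
                base_params.econ.screening_start_age,
                base_params.econ.screening_stop_age,
            )


class TestPositivity:
    @pytest.mark.parametrize(
        "test,state,expected",
        [
            (FOBT, S.PRECLIN_LOCAL, 0.72),
            (FOBT, S.PRECLIN_DISTANT, 0.72),
            (FOBT, S.NORMAL, 0.09),  # 1 - specificity
            (FOBT, S.LOW_POLYP, 0.03),
            (FOBT, S.HIGH_POLYP, 0.34),
            (SIGMOIDOSCOPY, S.HIGH_POLYP, 0.97 * 0.79),  # within-reach factor
            (SIGMOIDOSCOPY, S.NORMAL, 0.0),
            (COLONOSCOPY, S.PRECLIN_REGIONAL, 0.93),
            (COLONOSCOPY, S.NORMAL, 0.0),
        ],
    )
    def test_examples(self, base_params, test, state, expected):
        assert positivity(test, state, base_params.tests) == pytest.approx(
            expected
        )

    def test_unknown_test_rejected(self, base_params):
        with pytest.raises(ParameterError):
            positivity("MRI", S.NORMAL, base_params.tests)

    def test_diagnosed_states_not_screenable(self, base_params):
        with pytest.raises(ParameterError):
            positivity(FOBT, S.CLIN_LOCAL_DX, base_params.tests)


class TestColonoscopyResolution:
    def test_perforation_death_rate(self, base_params):
        res = colonoscopy_resolution(S.NORMAL, base_params)
        assert res.p_perforation_death == pytest.approx(0.0008 * 0.012)

    def test_low_risk_polyp_removal(self, base_params):
        res = colonoscopy_resolution(S.LOW_POLYP, base_params)
        live = 1 - res.p_perforation_death
        assert res.outcomes[S.NORMAL] == pytest.approx(live * 0.92)
        assert res.outcomes[S.LOW_POLYP] == pytest.approx(live * 0.08)

    def test_normal_mucosa_unchanged_with_cost(self, base_params):
        res = colonoscopy_resolution(S.NORMAL, base_params)
        assert res.outcomes[S.NORMAL] == pytest.approx(1 - res.p_perforation_death)
        assert res.expected_cost == pytest.approx(100 + 0.0008 * 500)
        assert res.detected_cancer_stage is None

    def test_preclinical_cancer_detected_to_screen_route(self, base_params):
        res = colonoscopy_resolution(S.PRECLIN_REGIONAL, base_params)
        assert res.detected_cancer_stage == "regional"
        live = 1 - res.p_perforation_death
        assert res.outcomes[S.CLIN_REGIONAL_SCR] == pytest.approx(live * 0.93)

    def test_surveillance_state_rejected(self, base_params):
        with pytest.raises(ParameterError):
            colonoscopy_resolution(S.SURVEILLANCE, base_params)


class TestApplyScreeningCycle:
    def test_no_screening_is_identity(self, base_params):
        ns = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "NO_SCREENING"
        )
        x = initial_distribution(base_params).x
        out = apply_screening_cycle(x, ns, 60, base_params)
        np.testing.assert_array_equal(out.post_screen, x)
        assert out.expected_cost == 0.0

    def test_off_schedule_year_is_identity(self, base_params):
        colo = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "COLO_10"
        )
        x = initial_distribution(base_params).x
        out = apply_screening_cycle(x, colo, 55, base_params)
        np.testing.assert_array_equal(out.post_screen, x)
        assert out.expected_cost == 0.0

    def test_fobt_cost_on_healthy_cohort(self, base_params):
        """Adherence x (test cost + false-positive confirmation chain)."""
        fobt = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "FOBT_ANNUAL"
        )
        out = apply_screening_cycle(all_normal(), fobt, 60, base_params)
        chain = 0.75 * 8 + 0.75 * 0.09 * 0.84 * 100
        assert out.expected_cost == pytest.approx(chain, rel=5e-3)
        # exact expectation includes perforation treatment on the cascade
        exact = 0.75 * 8 + 0.75 * 0.09 * 0.84 * (100 + 0.0008 * 500)
        assert out.expected_cost == pytest.approx(exact, abs=1e-12)

    def test_mass_conserved_up_to_perforation_deaths(self, base_params):
        colo = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "COLO_10"
        )
        x = initial_distribution(base_params).x
        out = apply_screening_cycle(x, colo, 50, base_params)
        assert out.post_screen.sum() == pytest.approx(1.0, abs=1e-12)
        assert out.expected_perforation_deaths > 0
        # deaths land in DEAD_OTHER
        assert out.post_screen[S.DEAD_OTHER] == pytest.approx(
            out.expected_perforation_deaths
        )

    def test_blind_tests_only_charge_primary_cost(self, base_params):
        """Zero sensitivity + perfect specificity: no state changes, no
        confirmatory cascade."""
        p = base_params.copy()
        t = p.tests
        t.fobt_sensitivity_low_polyp = 0.0
        t.fobt_sensitivity_high_polyp = 0.0
        t.fobt_sensitivity_cancer = 0.0
        t.fobt_specificity = 1.0
        fobt = next(s for s in builtin_strategies(p.econ) if s.name == "FOBT_ANNUAL")
        x = initial_distribution(p).x
        out = apply_screening_cycle(x, fobt, 60, p)
        np.testing.assert_allclose(out.post_screen, x, atol=1e-15)
        assert out.expected_cost == pytest.approx(0.75 * 8)

    def test_detected_cancers_reported_by_stage(self, base_params):
        colo = next(
            s for s in builtin_strategies(base_params.econ) if s.name == "COLO_10"
        )
        x = initial_distribution(base_params).x
        out = apply_screening_cycle(x, colo, 50, base_params)
        live = 1 - 0.0008 * 0.012
        assert out.cancers_detected_by_stage["localized"] == pytest.approx(
            0.0024 * 0.8 * 0.93 * live
        )


class TestAdherenceZeroEquivalence:
    @pytest.mark.parametrize("mode", ["persistent", "per_event"])
    def test_zero_adherence_matches_no_screening(
        self, base_params, life_table, mode
    ):
        p = base_params.copy()
        p.adherence.adherence_fobt = 0.0
        p.adherence.adherence_sigmo_fobt = 0.0
        p.adherence.adherence_colonoscopy = 0.0
        p.adherence.adherence_mode = mode
        strategies = builtin_strategies(p.econ)
        baseline = run_cohort(p, None, life_table)
        for strat in strategies:
            res = run_cohort(p, strat, life_table)
            assert res.discounted_cost == pytest.approx(
                baseline.discounted_cost, abs=1e-9
            )
            assert res.discounted_qalys == pytest.approx(
                baseline.discounted_qalys, abs=1e-12
            )
            assert res.lifetime_crc_deaths == pytest.approx(
                baseline.lifetime_crc_deaths, abs=1e-12
            )


class TestStageShiftBenefit:
    def test_colonoscopy_reduces_distant_disease(self, base_results):
        """10-yearly colonoscopy must lower cumulative clinical-disseminated
        incidence relative to no screening."""
        ns = base_results["NO_SCREENING"]
        colo = base_results["COLO_10"]
        dist_ns = ns.trace_public[:, HealthState.CLIN_DISTANT].sum()
        dist_colo = colo.trace_public[:, HealthState.CLIN_DISTANT].sum()
        assert dist_colo < dist_ns
        assert colo.lifetime_crc_deaths < ns.lifetime_crc_deaths
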