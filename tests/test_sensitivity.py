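"""Sensitivity machinery: sweeps, tornado, threshold search, scenario."""

import numpy as np
import pytest

from crcscreen.params import ParameterError, set_param
from crcscreen.sensitivity import (
    evaluate_pipeline,
    multi_way,
    one_way,
    scenario_low_treatment_adherence,
    threshold_search,
    tornado,
)


@pytest.fixture(scope="module")
def base_outcome(base_params, life_table):
    return evaluate_pipeline(base_params, life_table)


class TestOneWay:
    def test_degenerate_range_gives_constant_outcomes(
        self, base_params, life_table
    ):
        sw = one_way(
            "costs.c_fobt", base_params, life_table,
            n_points=3, value_range=(8.0, 8.0),
        )
        margins = [o.nmb_margin() for o in sw.outcomes]
        assert max(margins) - min(margins) == pytest.approx(0.0, abs=1e-9)

    def test_unknown_parameter_rejected(self, base_params, life_table):
        with pytest.raises(ParameterError):
            one_way("costs.nope", base_params, life_table)

    def test_treatment_cost_never_changes_decision(self, base_params, life_table):
        sw = one_way(
            "costs.c_treat_disseminated", base_params, life_table, n_points=5
        )
        assert {o.optimal for o in sw.outcomes} == {"COLO_10"}

    def test_surveillance_cost_never_changes_decision(self, base_params, life_table):
        sw = one_way(
            "costs.c_surveillance_per_year", base_params, life_table, n_points=5
        )
        assert {o.optimal for o in sw.outcomes} == {"COLO_10"}


@pytest.fixture(scope="module")
def bars(base_params, life_table):
    ids = [
        "costs.c_colonoscopy",
        "adherence.adherence_colonoscopy",
        "costs.c_treat_disseminated",
        "tests.fobt_sensitivity_cancer",
        "utilities.u_disseminated_cancer",
        "natural_history.p_low_to_high",
    ]
    return tornado(base_params, life_table, param_ids=ids)


class TestTornado:
    def test_influential_parameters_rank_top(self, bars):
        top2 = set(bars["param_id"].head(2))
        assert "costs.c_colonoscopy" in top2
        assert "adherence.adherence_colonoscopy" in top2

    def test_spans_match_independent_reevaluation(
        self, bars, base_params, life_table
    ):
        row = bars[bars.param_id == "costs.c_colonoscopy"].iloc[0]
        lo_m = evaluate_pipeline(
            set_param(base_params, "costs.c_colonoscopy", row.low_value), life_table
        ).nmb_margin()
        hi_m = evaluate_pipeline(
            set_param(base_params, "costs.c_colonoscopy", row.high_value), life_table
        ).nmb_margin()
        assert row.span == pytest.approx(abs(hi_m - lo_m), abs=1e-9)

    def test_inert_parameter_has_zero_span_and_ranks_last(
        self, base_params, life_table
    ):
        p = base_params.copy()
        p.ranges["costs.c_fobt"] = (8.0, 8.0)  # zero-width interval
        bars = tornado(
            p, life_table,
            param_ids=["costs.c_fobt", "costs.c_colonoscopy"],
        )
        assert bars.iloc[-1].param_id == "costs.c_fobt"
        assert bars.iloc[-1].span == pytest.approx(0.0, abs=1e-9)

    def test_empty_ranges_rejected(self, base_params, life_table):
        with pytest.raises(ParameterError):
            tornado(base_params, life_table, param_ids=[])


class TestThresholdSearch:
    def test_planted_breakpoint_recovered(self, base_params, life_table):
        """A synthetic decision flipping at a planted parameter value must
        be recovered within the bisection tolerance.  The decision compares
        COLO_10's cost (strictly increasing in the colonoscopy price) to its
        cost at the planted value, so the flip sits exactly there."""
        planted = 163.7
        cost_at_plant = _colo_cost_at(base_params, life_table, planted)
        res = threshold_search(
            "costs.c_colonoscopy",
            (30, 300),
            base_params,
            life_table,
            decision=lambda o: o.table.row("COLO_10").cost > cost_at_plant,
            tolerance=1.0,
        )
        assert res.breakpoint == pytest.approx(planted, abs=1.0)

    def test_adherence_threshold_flips_preferred_strategy(
        self, base_params, life_table
    ):
        res = threshold_search(
            "adherence.adherence_colonoscopy", (0.4, 0.8), base_params, life_table
        )
        assert res.below == "SIGMO_FOBT"
        assert res.above == "COLO_10"
        assert res.bracket[1] - res.bracket[0] <= res.tolerance

    def test_no_flip_raises(self, base_params, life_table):
        with pytest.raises(ParameterError, match="identical at both bounds"):
            threshold_search(
                "costs.c_fobt", (5, 20), base_params, life_table
            )

    def test_consistent_with_one_way_sweep(self, base_params, life_table):
        """The breakpoint must sit between the last grid value preferring
        one strategy and the first preferring the other."""
        res = threshold_search(
            "adherence.adherence_colonoscopy", (0.4, 0.8), base_params, life_table
        )
        sw = one_way(
            "adherence.adherence_colonoscopy", base_params, life_table,
            n_points=9, value_range=(0.4, 0.8),
        )
        opt = [o.optimal for o in sw.outcomes]
        flips = [
            (v1 + v2) / 2
            for v1, v2, o1, o2 in zip(
                sw.values, sw.values[1:], opt, opt[1:]
            )
            if o1 != o2
        ]
        assert len(flips) == 1
        step = sw.values[1] - sw.values[0]
        assert abs(res.breakpoint - flips[0]) <= step / 2 + res.tolerance


def _colo_cost_at(params, life_table, value):
    from crcscreen.cohort import run_cohort
    from crcscreen.screening import builtin_strategies

    cache = _colo_cost_at.__dict__.setdefault("cache", {})
    if value not in cache:
        p = set_param(params, "costs.c_colonoscopy", value)
        colo = next(s for s in builtin_strategies(p.econ) if s.name == "COLO_10")
        cache[value] = run_cohort(p, colo, life_table).discounted_cost
    return cache[value]


class TestMultiWay:
    def test_point_grid_equals_base_decision(
        self, base_params, life_table, base_outcome
    ):
        df = multi_way(
            ["costs.c_colonoscopy", "adherence.adherence_colonoscopy"],
            [np.array([100.0]), np.array([0.8])],
            base_params,
            life_table,
        )
        assert len(df) == 1
        assert df.iloc[0]["optimal"] == base_outcome.optimal

    def test_cells_are_referentially_transparent(self, base_params, life_table):
        df = multi_way(
            ["costs.c_colonoscopy", "adherence.adherence_colonoscopy"],
            [np.array([100.0, 250.0]), np.array([0.5, 0.8])],
            base_params,
            life_table,
        )
        for _, row in df.iterrows():
            p = set_param(base_params, "costs.c_colonoscopy", row["costs.c_colonoscopy"])
            p = set_param(
                p, "adherence.adherence_colonoscopy",
                row["adherence.adherence_colonoscopy"],
            )
            standalone = evaluate_pipeline(p, life_table)
            assert standalone.optimal == row["optimal"]

    def test_decision_boundary_consistent_with_one_way_slice(
        self, base_params, life_table
    ):
        """Along the base-case cost row, the 2-way grid must flip where the
        1-way adherence analysis flips."""
        grid_adh = np.linspace(0.4, 0.8, 9)
        df = multi_way(
            ["costs.c_colonoscopy", "adherence.adherence_colonoscopy"],
            [np.array([100.0]), grid_adh],
            base_params,
            life_table,
        )
        sw = one_way(
            "adherence.adherence_colonoscopy", base_params, life_table,
            n_points=9, value_range=(0.4, 0.8),
        )
        assert list(df["optimal"]) == [o.optimal for o in sw.outcomes]

    def test_wrong_arity_rejected(self, base_params, life_table):
        with pytest.raises(ParameterError):
            multi_way(["costs.c_fobt"], [np.array([8.0])], base_params, life_table)

    def test_oversized_grid_rejected(self, base_params, life_table):
        with pytest.raises(ParameterError, match="cells"):
            multi_way(
                ["costs.c_fobt", "costs.c_colonoscopy"],
                [np.arange(100.0), np.arange(100.0)],
                base_params,
                life_table,
                max_cells=50,
            )


class TestScenario:
    def test_differs_only_in_treatment_receipt(self, base_params):
        low = scenario_low_treatment_adherence(base_params)
        assert low.mortality.treatment_receipt_probability == 0.75
        d1, d2 = low.to_dict(), base_params.to_dict()
        d1["mortality"]["treatment_receipt_probability"] = d2["mortality"][
            "treatment_receipt_probability"
        ]
        assert d1 == d2

    def test_full_receipt_recovers_base_case(self, base_params, life_table):
        same = scenario_low_treatment_adherence(base_params, treatment_receipt=1.0)
        a = evaluate_pipeline(same, life_table)
        b = evaluate_pipeline(base_params, life_table)
        for ra, rb in zip(a.table.rows, b.table.rows):
            assert ra.cost == pytest.approx(rb.cost, abs=1e-9)
            assert ra.qalys == pytest.approx(rb.qalys, abs=1e-12)

    def test_colonoscopy_still_optimal_with_larger_mortality_benefit(
        self, base_params, life_table, base_outcome
    ):
        low = scenario_low_treatment_adherence(base_params)
        out = evaluate_pipeline(low, life_table)
        assert out.optimal == "COLO_10"
        base_mort = base_outcome.table.row("COLO_10").mortality_reduction_pct
        assert out.table.row("COLO_10").mortality_reduction_pct > base_mort
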