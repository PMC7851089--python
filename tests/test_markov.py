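"""Markov engine: probability conversion, transition structure, accrual."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import poccea
from poccea.states import STATE_INDEX, STATE_NAMES

from conftest import make_toy_model


class TestAnnualToCycleProb:
    @pytest.mark.parametrize(
        "p_annual, months, expected",
        [
            (0.0, 3, 0.0),
            (1.0, 3, 1.0),
            # closed form 1 - (1-p)^(m/12) on the hospitalization and
            # diabetic-foot annual occurrence probabilities
            (0.1895, 3, 1.0 - (1.0 - 0.1895) ** 0.25),
            (0.0310, 3, 1.0 - (1.0 - 0.0310) ** 0.25),
            (0.5, 12, 0.5),
            (0.75, 6, 0.5),
        ],
    )
    def test_matches_constant_rate_conversion(self, p_annual, months, expected):
        assert poccea.annual_to_cycle_prob(p_annual, months) == pytest.approx(
            expected, abs=1e-12
        )

    def test_quarterly_values_frozen_oracle(self):
        # frozen from the closed form evaluated independently
        assert poccea.annual_to_cycle_prob(0.1895, 3) == pytest.approx(
            0.0511703340830546, abs=1e-12
        )
        assert poccea.annual_to_cycle_prob(0.0310, 3) == pytest.approx(
            0.0078417584951597, abs=1e-12
        )

    @given(
        p1=st.floats(0.0, 0.99),
        p2=st.floats(0.0, 0.99),
        months=st.floats(0.5, 12.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_bounded_and_monotone(self, p1, p2, months):
        lo, hi = sorted((p1, p2))
        qlo = poccea.annual_to_cycle_prob(lo, months)
        qhi = poccea.annual_to_cycle_prob(hi, months)
        assert 0.0 <= qlo <= qhi <= 1.0

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            poccea.annual_to_cycle_prob(1.3, 3)
        with pytest.raises(ValueError):
            poccea.annual_to_cycle_prob(0.5, 0)


class TestDiscountFactor:
    def test_reference_values(self):
        assert poccea.discount_factor(0.04, 0.0) == 1.0
        assert poccea.discount_factor(0.04, 1.0) == pytest.approx(1 / 1.04)
        assert poccea.discount_factor(0.04, 10.0) == pytest.approx(1.04**-10)

    def test_strictly_decreasing_and_domain(self):
        assert poccea.discount_factor(0.04, 2.0) < poccea.discount_factor(0.04, 1.0)
        with pytest.raises(ValueError):
            poccea.discount_factor(0.04, -1.0)


class TestTransitionMatrix:
    def test_zero_hazards_gives_identity_except_resolving_rows(self):
        config = make_toy_model(control_prob=0.0)
        m = poccea.build_transition_matrix(config, config.strategies[0])
        expected = np.eye(len(STATE_NAMES))
        # hospitalization structurally resolves to uncontrolled
        h = STATE_INDEX["hospitalization"]
        expected[h, h] = 0.0
        expected[h, STATE_INDEX["uncontrolled"]] = 1.0
        assert np.allclose(m.probs, expected)

    def test_reference_rows_sum_to_one(self, model):
        for strategy in model.strategies:
            m = poccea.build_transition_matrix(model, strategy)
            assert np.allclose(m.probs.sum(axis=1), 1.0, atol=1e-12)

    def test_control_entry_uses_per_cycle_rate(self, model):
        # with competing complication hazards the control transition is the
        # nominal 0.14 scaled by the joint-event normalization, slightly below
        m = poccea.build_transition_matrix(model, model.strategy("poc"))
        entry = m["uncontrolled", "controlled"]
        assert 0.85 * 0.14 < entry <= 0.14
        no_comp = make_toy_model(control_prob=0.14)
        m2 = poccea.build_transition_matrix(no_comp, no_comp.strategies[0])
        assert m2["uncontrolled", "controlled"] == pytest.approx(0.14, abs=1e-15)

    def test_dead_row_absorbing(self, model):
        m = poccea.build_transition_matrix(model, model.strategy("poc"))
        i = STATE_INDEX["dead"]
        expected = np.zeros(len(STATE_NAMES))
        expected[i] = 1.0
        assert np.array_equal(m.probs[i], expected)

    def test_hospitalization_resolves_to_uncontrolled(self, model):
        m = poccea.build_transition_matrix(model, model.strategy("poc"))
        h = STATE_INDEX["hospitalization"]
        assert m.probs[h, STATE_INDEX["uncontrolled"]] > 0
        assert m.probs[h, h] == 0.0

    def test_oversubscribed_row_raises(self):
        config = make_toy_model(
            control_prob=0.9, occurrence={"hospitalization": 0.9, "cvd": 0.9}
        )
        with pytest.raises(poccea.ConfigurationError, match="uncontrolled"):
            poccea.build_transition_matrix(config, config.strategies[0])


class TestRunCohort:
    def test_identity_matrix_keeps_cohort_in_entry_state(self):
        config = make_toy_model(control_prob=0.0)
        m = poccea.build_transition_matrix(config, config.strategies[0])
        trace = poccea.run_cohort(m, config)
        assert np.all(trace.state("uncontrolled") == 1.0)

    def test_two_state_geometric_closed_form(self):
        # uncontrolled -> controlled with p = 0.5, controlled absorbing
        config = make_toy_model(control_prob=0.5)
        m = poccea.build_transition_matrix(config, config.strategies[0])
        trace = poccea.run_cohort(m, config)
        k = np.arange(trace.n_cycles + 1)
        assert np.allclose(trace.state("uncontrolled"), 0.5**k, atol=1e-10)

    def test_three_state_competing_risk_closed_form(self):
        # uncontrolled -> {controlled, cvd(chronic, no death)}: occupancies
        # follow the allocated-geometric closed form
        config = make_toy_model(control_prob=0.3, occurrence={"cvd": 0.2})
        strategy = config.strategies[0]
        m = poccea.build_transition_matrix(config, strategy)
        trace = poccea.run_cohort(m, config)
        q = 1.0 - (1.0 - 0.2) ** 0.25
        p_any = 1.0 - (1.0 - 0.3) * (1.0 - q)
        share_ctrl = 0.3 / (0.3 + q) * p_any
        share_cvd = q / (0.3 + q) * p_any
        k = np.arange(trace.n_cycles + 1)
        stay = (1.0 - p_any) ** k
        assert np.allclose(trace.state("uncontrolled"), stay, atol=1e-10)
        assert np.allclose(
            trace.state("controlled"), share_ctrl / p_any * (1 - stay), atol=1e-10
        )
        assert np.allclose(
            trace.state("cvd"), share_cvd / p_any * (1 - stay), atol=1e-10
        )

    def test_reference_trace_shape_and_times(self, model):
        m = poccea.build_transition_matrix(model, model.strategy("poc"))
        trace = poccea.run_cohort(m, model)
        assert trace.occupancy.shape == (41, len(STATE_NAMES))
        assert trace.cycle_times[-1] == pytest.approx(10.0)

    @given(
        control=st.floats(0.0, 0.3),
        occ_cvd=st.floats(0.0, 0.3),
        occ_hosp=st.floats(0.0, 0.3),
        death_cvd=st.floats(0.0, 0.5),
        rr=st.floats(0.0, 1.0),
        relapse=st.floats(0.0, 0.2),
    )
    @settings(derandomize=True, max_examples=30, deadline=None)
    def test_mass_conserved_and_death_monotone(
        self, control, occ_cvd, occ_hosp, death_cvd, rr, relapse
    ):
        config = make_toy_model(
            control_prob=control,
            occurrence={"cvd": occ_cvd, "hospitalization": occ_hosp},
            death={"cvd": death_cvd, "hospitalization": 0.1},
            rr_controlled=rr,
            relapse=relapse,
        )
        m = poccea.build_transition_matrix(config, config.strategies[0])
        trace = poccea.run_cohort(m, config)
        assert np.allclose(trace.occupancy.sum(axis=1), 1.0, atol=1e-10)
        dead = trace.state("dead")
        assert np.all(np.diff(dead) >= -1e-12)


class TestAccrueOutcomes:
    def _outcome(self, config, strategy=None):
        strategy = strategy or config.strategies[0]
        m = poccea.build_transition_matrix(config, strategy)
        trace = poccea.run_cohort(m, config)
        return poccea.accrue_outcomes(trace, config, strategy)

    def test_zero_costs_accrue_zero(self):
        out = self._outcome(make_toy_model())
        assert out.discounted_cost == 0.0

    def test_single_state_undiscounted_annuity(self):
        # cohort stays in one state costing C/yr for 10 years, no discounting
        out = self._outcome(
            make_toy_model(control_prob=0.0, general_annual_cost=123.4)
        )
        assert out.discounted_cost == pytest.approx(10 * 123.4, rel=1e-12)

    def test_discounting_reduces_cost(self):
        undiscounted = self._outcome(
            make_toy_model(control_prob=0.0, general_annual_cost=1000.0)
        )
        discounted = self._outcome(
            make_toy_model(
                control_prob=0.0,
                general_annual_cost=1000.0,
                annual_discount_rate=0.04,
            )
        )
        assert undiscounted.discounted_cost > discounted.discounted_cost

    def test_half_cycle_correction_between_conventions(self, model):
        strategy = model.strategy("poc")
        m = poccea.build_transition_matrix(model, strategy)
        trace = poccea.run_cohort(m, model)
        corrected = poccea.accrue_outcomes(trace, model, strategy).discounted_cost
        uncorrected = model.copy()
        uncorrected.half_cycle_correction = False
        start = poccea.accrue_outcomes(
            trace, uncorrected, strategy
        ).discounted_cost
        # end-of-cycle convention computed independently from the trace
        from poccea.markov import _state_cost_per_cycle

        costs = _state_cost_per_cycle(model, strategy)
        df = (1 + model.annual_discount_rate) ** (-trace.cycle_times)
        boundary = (trace.occupancy @ costs) * df
        end = boundary[1:].sum()
        lo, hi = sorted((start, end))
        assert lo <= corrected <= hi

    def test_effectiveness_definitions_consistent(self, model):
        strategy = model.strategy("poc")
        m = poccea.build_transition_matrix(model, strategy)
        trace = poccea.run_cohort(m, model)
        effs = {}
        for definition in (
            "at_eval_point",
            "cumulative_ever",
            "access_adjusted_attainment",
        ):
            variant = model.copy()
            variant.effectiveness_definition = definition
            effs[definition] = poccea.accrue_outcomes(
                trace, variant, strategy
            ).effectiveness
        # controlled patients can still develop complications (rr > 0), so
        # point occupancy cannot exceed the cumulative attainment
        assert effs["at_eval_point"] <= effs["cumulative_ever"] + 1e-12
        # access adjustment and discounting can only lower the endpoint
        assert effs["access_adjusted_attainment"] < effs["cumulative_ever"]
        assert 0.0 <= effs["access_adjusted_attainment"] <= 1.0

    def test_attainment_matches_geometric_formula(self, model):
        # independent arithmetic for the access-adjusted endpoint
        strategy = model.strategy("lab")
        m = poccea.build_transition_matrix(model, strategy)
        trace = poccea.run_cohort(m, model)
        out = poccea.accrue_outcomes(trace, model, strategy)
        p, avail = 0.0738, 0.36
        expected = avail * sum(
            (1 - p) ** (j - 1) * p * 1.04 ** (-j / 4) for j in range(1, 5)
        )
        assert out.effectiveness == pytest.approx(expected, rel=1e-12)

    def test_raising_control_rate_never_hurts(self, model):
        # higher per-cycle control probability: effectiveness up, complication
        # occupancy (hence complication-cost accrual) down
        def run(p):
            variant = model.copy()
            strat = variant.strategy("poc")
            strat.control_prob_per_cycle = p
            m = poccea.build_transition_matrix(variant, strat)
            trace = poccea.run_cohort(m, variant)
            out = poccea.accrue_outcomes(trace, variant, strat)
            comp_occ = sum(
                trace.state(c).sum()
                for c in ("cvd", "retinopathy", "nephropathy", "diabetic_foot",
                          "hospitalization")
            )
            return out.effectiveness, comp_occ

        grid = [0.05, 0.10, 0.14, 0.20, 0.40]
        results = [run(p) for p in grid]
        effs = [r[0] for r in results]
        occs = [r[1] for r in results]
        assert all(a <= b + 1e-12 for a, b in zip(effs, effs[1:]))
        assert all(a >= b - 1e-12 for a, b in zip(occs, occs[1:]))

    def test_dimension_mismatch_rejected(self, model):
        strategy = model.strategy("poc")
        m = poccea.build_transition_matrix(model, strategy)
        trace = poccea.run_cohort(m, model)
        short = model.copy()
        short.horizon_years = 5.0
        with pytest.raises(ValueError, match="cycles"):
            poccea.accrue_outcomes(trace, short, strategy)


class TestEvaluateStrategies:
    def test_reference_returns_both_strategies(self, reference_outcomes):
        assert [o.strategy for o in reference_outcomes] == ["poc", "lab"]

    def test_identical_strategies_identical_outcomes(self):
        config = make_toy_model(
            control_prob=0.14, occurrence={"cvd": 0.129}, death={"cvd": 0.284},
            general_annual_cost=1844.0, annual_discount_rate=0.04,
            test_cost=2.65,
        )
        a, b = poccea.evaluate_strategies(config)
        assert a.discounted_cost == b.discounted_cost
        assert a.effectiveness == b.effectiveness
        assert np.array_equal(a.trace.occupancy, b.trace.occupancy)
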