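import pytest

import poccea


@pytest.fixture(scope="session")
def reference():
    """Packaged reference configuration (model + cohort + sensitivity opts)."""
    return poccea.reference_config()


@pytest.fixture(scope="session")
def model(reference):
    return reference["model"]


@pytest.fixture(scope="session")
def reference_outcomes(model):
    """Deterministic strategy outcomes under the reference parameterization."""
    return poccea.evaluate_strategies(model)


def make_toy_model(
    control_prob=0.5,
    occurrence=None,
    death=None,
    general_annual_cost=0.0,
    annual_discount_rate=0.0,
    horizon_years=10.0,
    test_cost=0.0,
    rr_controlled=0.0,
    relapse=0.0,
    half_cycle_correction=True,
    effectiveness_definition="cumulative_ever",
    effectiveness_eval_cycles=2,
    p_result_available=1.0,
    control_prob_b=None,
):
    """Small two-strategy model with every hazard off unless supplied."""
    occurrence = occurrence or {}
    death = death or {}
    states = [
        poccea.StateSpec("uncontrolled", accrues_general_cost=True, chronic=False),
        poccea.StateSpec("controlled", accrues_general_cost=True, chronic=False),
    ]
    for name in ("cvd", "retinopathy", "nephropathy", "diabetic_foot"):
        states.append(
            poccea.StateSpec(name, death_prob_annual=death.get(name, 0.0))
        )
    states.append(
        poccea.StateSpec(
            "hospitalization",
            death_prob_annual=death.get("hospitalization", 0.0),
            chronic=False,
        )
    )
    strategies = [
        poccea.StrategySpec(
            name="a",
            control_prob_per_cycle=control_prob,
            test_cost_per_test=test_cost,
            p_result_available=p_result_available,
        ),
        poccea.StrategySpec(
            name="b",
            control_prob_per_cycle=(
                control_prob if control_prob_b is None else control_prob_b
            ),
            test_cost_per_test=test_cost,
            p_result_available=p_result_available,
        ),
    ]
    return poccea.ModelConfig(
        horizon_years=horizon_years,
        annual_discount_rate=annual_discount_rate,
        general_annual_cost=general_annual_cost,
        occurrence_probs_annual=occurrence,
        complication_risk_rr_controlled=rr_controlled,
        relapse_prob_per_cycle=relapse,
        half_cycle_correction=half_cycle_correction,
        effectiveness_definition=effectiveness_definition,
        effectiveness_eval_cycles=effectiveness_eval_cycles,
        state_specs=states,
        strategies=strategies,
    )


@pytest.fixture
def toy_model():
    return make_toy_model()
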