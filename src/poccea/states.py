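"""Health-state space of the diabetes monitoring model.

The cohort moves between glycemic-control states (``uncontrolled``,
``controlled``), chronic complication states that persist once entered
(cardiovascular disease, retinopathy, nephropathy, diabetic foot), a
transient one-cycle ``hospitalization`` state, and an absorbing ``dead``
state.
"""

from __future__ import annotations

from dataclasses import dataclass

UNCONTROLLED = "uncontrolled"
CONTROLLED = "controlled"
CVD = "cvd"
RETINOPATHY = "retinopathy"
NEPHROPATHY = "nephropathy"
DIABETIC_FOOT = "diabetic_foot"
HOSPITALIZATION = "hospitalization"
DEAD = "dead"

#: Canonical state ordering used by every transition matrix and cohort trace.
STATE_NAMES: tuple[str, ...] = (
    UNCONTROLLED,
    CONTROLLED,
    CVD,
    RETINOPATHY,
    NEPHROPATHY,
    DIABETIC_FOOT,
    HOSPITALIZATION,
    DEAD,
)

#: Complication states a patient can transition into from the control states.
COMPLICATIONS: tuple[str, ...] = (
    CVD,
    RETINOPATHY,
    NEPHROPATHY,
    DIABETIC_FOOT,
    HOSPITALIZATION,
)

STATE_INDEX: dict[str, int] = {name: i for i, name in enumerate(STATE_NAMES)}

#: Per-admission sub-costs of the diabetic-foot complication (US$/patient/year):
#: healing, minor amputation, major amputation. The model uses their mean.
DIABETIC_FOOT_SUBCOSTS: tuple[float, float, float] = (162.10, 112.90, 223.80)


def diabetic_foot_cost(subcosts: tuple[float, ...] = DIABETIC_FOOT_SUBCOSTS) -> float:
    """Mean of the diabetic-foot sub-costs, the model's state cost."""
    return sum(subcosts) / len(subcosts)


@dataclass(frozen=True)
class StateSpec:
    """Cost and mortality attached to one health state.

    Parameters
    ----------
    state:
        State name, one of :data:`STATE_NAMES`.
    annual_cost:
        Complication-specific cost in US$ per patient-year accrued while
        occupying the state.
    death_prob_annual:
        Annual case-fatality probability for occupants of the state.
    chronic:
        Whether the state persists once entered.  Non-chronic states
        (hospitalization) resolve back to ``uncontrolled`` after one cycle.
    accrues_general_cost:
        Whether occupants additionally accrue the general diabetes-care
        cost.  In the reference parameterization only the two control
        states do; complication-state costs are interpreted as
        all-inclusive annual care costs.
    """

    state: str
    annual_cost: float = 0.0
    death_prob_annual: float = 0.0
    chronic: bool = True
    accrues_general_cost: bool = False

    def __post_init__(self) -> None:
        if self.state not in STATE_NAMES:
            raise ValueError(f"unknown state name {self.state!r}")
        if self.annual_cost < 0:
            raise ValueError(f"state {self.state}: annual_cost must be >= 0")
        if not 0.0 <= self.death_prob_annual <= 1.0:
            raise ValueError(
                f"state {self.state}: death_prob_annual must be in [0, 1]"
            )
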