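"""Markov cohort engine: transition matrices, cohort traces, outcome accrual.

The cohort enters entirely in the ``uncontrolled`` state and progresses in
3-month cycles.  Per cycle an uncontrolled patient faces competing
transitions: reaching the glycemic target (strategy-specific per-cycle
probability), developing one of the chronic complications, a one-cycle
hospitalization, or background death.  Patients at target face the same
complication hazards scaled by a relative-risk factor.  Chronic states
persist and carry an annual case-fatality; hospitalization resolves back to
``uncontrolled``.  Costs and outcomes are discounted at an annual rate with
a trapezoidal half-cycle correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ConfigurationError, ModelConfig, StrategySpec
from .states import (
    COMPLICATIONS,
    CONTROLLED,
    DEAD,
    STATE_INDEX,
    STATE_NAMES,
    UNCONTROLLED,
)

__all__ = [
    "annual_to_cycle_prob",
    "discount_factor",
    "TransitionMatrix",
    "CohortTrace",
    "StrategyOutcome",
    "build_transition_matrix",
    "run_cohort",
    "accrue_outcomes",
    "evaluate_strategies",
]


def annual_to_cycle_prob(p_annual: float, cycle_length_months: float) -> float:
    """Convert an annual probability to a per-cycle probability.

    Assumes a constant hazard within the year:
    ``1 - (1 - p_annual) ** (cycle_length_months / 12)``.
    """
    if not 0.0 <= p_annual <= 1.0:
        raise ValueError(f"p_annual={p_annual!r} must be in [0, 1]")
    if cycle_length_months <= 0:
        raise ValueError("cycle_length_months must be > 0")
    if p_annual == 1.0:
        return 1.0
    return 1.0 - (1.0 - p_annual) ** (cycle_length_months / 12.0)


def discount_factor(annual_rate: float, t: float) -> float:
    """Discount factor ``(1 + annual_rate) ** -t`` at ``t`` years."""
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    if t < 0:
        raise ValueError(f"t={t!r}: time must be >= 0")
    return (1.0 + annual_rate) ** (-t)


@dataclass(frozen=True)
class TransitionMatrix:
    """Per-cycle transition probabilities over :data:`~poccea.states.STATE_NAMES`."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        n = len(STATE_NAMES)
        if self.probs.shape != (n, n):
            raise ValueError(f"transition matrix must be {n}x{n}")
        if np.any(self.probs < -1e-12) or np.any(self.probs > 1 + 1e-12):
            raise ValueError("transition probabilities must be in [0, 1]")
        rows = self.probs.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-12):
            bad = STATE_NAMES[int(np.argmax(np.abs(rows - 1.0)))]
            raise ValueError(f"row {bad!r} does not sum to 1 (got {rows})")

    def __getitem__(self, key: tuple[str, str]) -> float:
        src, dst = key
        return float(self.probs[STATE_INDEX[src], STATE_INDEX[dst]])


@dataclass(frozen=True)
class CohortTrace:
    """State-occupancy fractions per cycle boundary for one strategy.

    ``occupancy[k, s]`` is the cohort fraction in state ``s`` at the start
    of cycle ``k`` (row 0 is model entry); ``cycle_times[k]`` is the
    corresponding time in years.
    """

    occupancy: np.ndarray
    cycle_times: np.ndarray

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def state(self, name: str) -> np.ndarray:
        return self.occupancy[:, STATE_INDEX[name]]

    def to_frame(self) -> pd.DataFrame:
        """Long-format export: ``cycle, time_years, state, occupancy``."""
        frames = []
        for name in STATE_NAMES:
            frames.append(
                pd.DataFrame(
                    {
                        "cycle": np.arange(self.occupancy.shape[0]),
                        "time_years": self.cycle_times,
                        "state": name,
                        "occupancy": self.state(name),
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted mean cost and effectiveness per patient for one strategy."""

    strategy: str
    discounted_cost: float
    effectiveness: float
    trace: CohortTrace


def _combine_competing(hazards: dict[str, float], row_name: str) -> dict[str, float]:
    """Allocate one cycle's competing event probabilities.

    Independent per-cycle hazards are combined multiplicatively — the
    probability of any event is ``1 - prod(1 - h_i)`` — and allocated to
    the individual events proportionally to their marginal hazards, so the
    row sums to one exactly.
    """
    probs = np.array(list(hazards.values()), dtype=float)
    total = probs.sum()
    if total > 1.0 + 1e-12:
        raise ConfigurationError(
            f"row {row_name!r}: summed competing per-cycle probabilities "
            f"exceed 1 ({total:.4f}); cannot be jointly normalized"
        )
    if total == 0.0:
        return {k: 0.0 for k in hazards}
    p_any = 1.0 - np.prod(1.0 - probs)
    return {k: h / total * p_any for k, h in hazards.items()}


def build_transition_matrix(
    config: ModelConfig, strategy: StrategySpec
) -> TransitionMatrix:
    """Assemble the per-cycle transition matrix for one strategy."""
    n = len(STATE_NAMES)
    m = np.zeros((n, n))
    months = config.cycle_length_months
    bg = annual_to_cycle_prob(config.background_death_prob_annual, months)
    occ_cycle = {
        c: annual_to_cycle_prob(config.occurrence_probs_annual.get(c, 0.0), months)
        for c in COMPLICATIONS
    }

    for src, extra, rr in (
        (UNCONTROLLED, {CONTROLLED: strategy.control_prob_per_cycle}, 1.0),
        (CONTROLLED, {UNCONTROLLED: config.relapse_prob_per_cycle},
         config.complication_risk_rr_controlled),
    ):
        hazards = {k: v for k, v in extra.items() if v > 0}
        hazards.update({c: occ_cycle[c] * rr for c in COMPLICATIONS})
        hazards[DEAD] = bg
        alloc = _combine_competing(hazards, src)
        i = STATE_INDEX[src]
        for dst, p in alloc.items():
            m[i, STATE_INDEX[dst]] += p
        m[i, i] += 1.0 - sum(alloc.values())

    for c in COMPLICATIONS:
        spec = config.state_spec(c)
        death = annual_to_cycle_prob(spec.death_prob_annual, months)
        p_dead = 1.0 - (1.0 - death) * (1.0 - bg)
        i = STATE_INDEX[c]
        m[i, STATE_INDEX[DEAD]] = p_dead
        persists = spec.chronic or (
            c == "hospitalization" and not config.hospitalization_resolves
        )
        if persists:
            m[i, i] += 1.0 - p_dead
        else:
            m[i, STATE_INDEX[UNCONTROLLED]] += 1.0 - p_dead

    m[STATE_INDEX[DEAD], STATE_INDEX[DEAD]] = 1.0
    return TransitionMatrix(probs=m)


def run_cohort(matrix: TransitionMatrix, config: ModelConfig) -> CohortTrace:
    """Propagate the cohort from all-uncontrolled entry over the horizon."""
    n_cycles = config.n_cycles
    occ = np.zeros((n_cycles + 1, len(STATE_NAMES)))
    occ[0, STATE_INDEX[UNCONTROLLED]] = 1.0
    for k in range(n_cycles):
        occ[k + 1] = occ[k] @ matrix.probs
    times = np.arange(n_cycles + 1) * config.cycle_length_years
    return CohortTrace(occupancy=occ, cycle_times=times)


def _state_cost_per_cycle(config: ModelConfig, strategy: StrategySpec) -> np.ndarray:
    """Per-cycle cost attached to each alive state, including testing."""
    frac = config.cycle_length_years
    test = strategy.cost_per_test * strategy.tests_per_cycle
    costs = np.zeros(len(STATE_NAMES))
    for name in STATE_NAMES:
        if name == DEAD:
            continue
        spec = config.state_spec(name)
        c = spec.annual_cost * frac
        if spec.accrues_general_cost:
            c += config.general_annual_cost * frac
        costs[STATE_INDEX[name]] = c + test
    return costs


def _ever_controlled(config: ModelConfig, strategy: StrategySpec) -> np.ndarray:
    """Cumulative probability of having reached the target by each cycle.

    Computed on a copy of the chain with the controlled state made
    absorbing, so re-entry after relapse is not double counted.
    """
    matrix = build_transition_matrix(config, strategy)
    m = matrix.probs.copy()
    i = STATE_INDEX[CONTROLLED]
    m[i] = 0.0
    m[i, i] = 1.0
    occ = np.zeros(len(STATE_NAMES))
    occ[STATE_INDEX[UNCONTROLLED]] = 1.0
    out = np.zeros(config.n_cycles + 1)
    for k in range(config.n_cycles):
        occ = occ @ m
        out[k + 1] = occ[i]
    return out


def _attainment_effectiveness(config: ModelConfig, strategy: StrategySpec) -> float:
    """Access-adjusted discounted probability of reaching the target.

    The probability that a patient has an A1c result available under the
    strategy, times the discounted probability of first reaching the A1c
    target at one of the quarterly assessments inside the evaluation
    window (constant per-cycle control probability).
    """
    p = strategy.control_prob_per_cycle
    frac = config.cycle_length_years
    total = 0.0
    for j in range(1, config.effectiveness_eval_cycles + 1):
        df = discount_factor(config.annual_discount_rate, j * frac)
        total += (1.0 - p) ** (j - 1) * p * df
    return strategy.p_result_available * total


def accrue_outcomes(
    trace: CohortTrace, config: ModelConfig, strategy: StrategySpec
) -> StrategyOutcome:
    """Discount and accumulate cost and effectiveness over the trace."""
    if trace.n_cycles != config.n_cycles:
        raise ValueError(
            f"trace has {trace.n_cycles} cycles but config specifies "
            f"{config.n_cycles}"
        )
    costs = _state_cost_per_cycle(config, strategy)
    df = np.array(
        [discount_factor(config.annual_discount_rate, t) for t in trace.cycle_times]
    )
    boundary = (trace.occupancy @ costs) * df
    if config.half_cycle_correction:
        total_cost = float(0.5 * (boundary[:-1] + boundary[1:]).sum())
    else:
        total_cost = float(boundary[:-1].sum())

    k_eval = config.effectiveness_eval_cycles
    definition = config.effectiveness_definition
    if definition == "at_eval_point":
        eff = float(trace.state(CONTROLLED)[k_eval])
    elif definition == "cumulative_ever":
        eff = float(_ever_controlled(config, strategy)[k_eval])
    elif definition == "discounted_time_in_control":
        in_control = trace.state(CONTROLLED) * df
        if config.half_cycle_correction:
            years = 0.5 * (in_control[:-1] + in_control[1:]).sum()
        else:
            years = in_control[:-1].sum()
        eff = float(years * config.cycle_length_years)
    elif definition == "access_adjusted_attainment":
        eff = _attainment_effectiveness(config, strategy)
    else:  # pragma: no cover - blocked by config validation
        raise ConfigurationError(
            f"model.effectiveness_definition={definition!r} unknown"
        )
    return StrategyOutcome(
        strategy=strategy.name,
        discounted_cost=total_cost,
        effectiveness=eff,
        trace=trace,
    )


def evaluate_strategies(config: ModelConfig) -> list[StrategyOutcome]:
    """Run the full pipeline for every configured strategy."""
    if len(config.strategies) < 2:
        raise ConfigurationError("strategies: at least 2 strategies required")
    outcomes = []
    for strategy in config.strategies:
        matrix = build_transition_matrix(config, strategy)
        trace = run_cohort(matrix, config)
        outcomes.append(accrue_outcomes(trace, config, strategy))
    return outcomes


def outcomes_to_frame(outcomes: list[StrategyOutcome]) -> pd.DataFrame:
    """Tabular export: ``strategy, discounted_cost, effectiveness``."""
    return pd.DataFrame(
        {
            "strategy": [o.strategy for o in outcomes],
            "discounted_cost": [o.discounted_cost for o in outcomes],
            "effectiveness": [o.effectiveness for o in outcomes],
        }
    )
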