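"""Incremental cost-effectiveness statistics and net monetary benefit."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import StrategyOutcome

__all__ = ["CEAComparison", "NMBPoint", "compare", "nmb_curve"]

DOMINANCE_NONE = "none"
DOMINANCE_INTERVENTION = "intervention_dominates"
DOMINANCE_COMPARATOR = "comparator_dominates"


@dataclass(frozen=True)
class CEAComparison:
    """Two-strategy incremental comparison.

    ``icer`` is delta_cost / delta_effect computed from full-precision
    deltas; it is ``None`` when one strategy dominates or when
    ``delta_effect`` is zero (undefined ratio).
    """

    intervention: StrategyOutcome
    comparator: StrategyOutcome
    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "intervention": self.intervention.strategy,
                    "comparator": self.comparator.strategy,
                    "delta_cost": self.delta_cost,
                    "delta_effect": self.delta_effect,
                    "icer": math.nan if self.icer is None else self.icer,
                    "dominance": self.dominance,
                }
            ]
        )


@dataclass(frozen=True)
class NMBPoint:
    """Net monetary benefit of each strategy at one willingness-to-pay."""

    wtp: float
    nmb_by_strategy: dict[str, float]
    incremental_nmb: float


def compare(
    intervention: StrategyOutcome, comparator: StrategyOutcome
) -> CEAComparison:
    """Incremental cost, incremental effectiveness, ICER and dominance.

    Dominance is classified on the strict sign quadrant: the intervention
    dominates when it is cheaper *and* more effective, the comparator when
    the reverse holds; equal outcomes are not dominance.
    """
    delta_cost = intervention.discounted_cost - comparator.discounted_cost
    delta_effect = intervention.effectiveness - comparator.effectiveness
    if delta_cost < 0 and delta_effect > 0:
        dominance = DOMINANCE_INTERVENTION
    elif delta_cost > 0 and delta_effect < 0:
        dominance = DOMINANCE_COMPARATOR
    else:
        dominance = DOMINANCE_NONE
    icer = None
    if dominance == DOMINANCE_NONE and delta_effect != 0.0:
        icer = delta_cost / delta_effect
    return CEAComparison(
        intervention=intervention,
        comparator=comparator,
        delta_cost=delta_cost,
        delta_effect=delta_effect,
        icer=icer,
        dominance=dominance,
    )


def nmb_curve(
    outcomes: list[StrategyOutcome], wtp_grid: list[float] | np.ndarray
) -> list[NMBPoint]:
    """Net monetary benefit ``wtp * effectiveness - cost`` over a WTP grid.

    ``incremental_nmb`` compares the first listed strategy (intervention)
    against the second (comparator); it crosses zero exactly at the ICER
    when dominance does not apply.
    """
    wtp_grid = list(wtp_grid)
    if not wtp_grid:
        raise ValueError("wtp_grid must be nonempty")
    if any(w < 0 for w in wtp_grid):
        raise ValueError("wtp values must be >= 0")
    if len(outcomes) < 2:
        raise ValueError("nmb_curve requires at least two strategies")
    points = []
    first, second = outcomes[0], outcomes[1]
    for wtp in wtp_grid:
        nmbs = {
            o.strategy: wtp * o.effectiveness - o.discounted_cost for o in outcomes
        }
        inc = wtp * (first.effectiveness - second.effectiveness) - (
            first.discounted_cost - second.discounted_cost
        )
        points.append(NMBPoint(wtp=float(wtp), nmb_by_strategy=nmbs,
                               incremental_nmb=inc))
    return points


def nmb_curve_frame(points: list[NMBPoint]) -> pd.DataFrame:
    """Long-format export: ``wtp, strategy, nmb, incremental_nmb``."""
    rows = []
    for pt in points:
        for strategy, nmb in pt.nmb_by_strategy.items():
            rows.append(
                {
                    "wtp": pt.wtp,
                    "strategy": strategy,
                    "nmb": nmb,
                    "incremental_nmb": pt.incremental_nmb,
                }
            )
    return pd.DataFrame(rows)
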