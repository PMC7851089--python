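"""Probabilistic (Monte Carlo) and deterministic one-way sensitivity analysis.

The PSA draws every uncertain parameter independently per trial — beta
distributions for probabilities, gamma for costs, parameterized by method
of moments from the base-case value and a relative dispersion — rebuilds
the model and re-evaluates both strategies.  The one-way analysis sweeps
each parameter across a low/high range with everything else at base case
and ranks parameters by the width of their effect on incremental net
monetary benefit at a fixed willingness-to-pay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import compare
from .config import (
    ConfigurationError,
    ModelConfig,
    ParamDistribution,
    get_param,
    set_param,
)
from .markov import evaluate_strategies
from .states import COMPLICATIONS

__all__ = [
    "PSAResult",
    "TornadoEntry",
    "default_distributions",
    "default_tornado_ranges",
    "run_psa",
    "tornado",
]

#: Default WTP grid (US$ per unit effectiveness) for acceptability curves.
DEFAULT_WTP_GRID = np.arange(0.0, 5001.0, 100.0)


def _table_parameter_paths(config: ModelConfig) -> list[str]:
    """Dotted paths of the literature parameter ledger (costs + probabilities)."""
    paths = [f"model.states.{c}.annual_cost" for c in COMPLICATIONS]
    paths.append("model.general_annual_cost")
    paths += [f"model.occurrence_probs_annual.{c}" for c in COMPLICATIONS]
    paths += [f"model.states.{c}.death_prob_annual" for c in COMPLICATIONS]
    return paths


def default_distributions(
    config: ModelConfig, dispersion: float = 0.2
) -> list[ParamDistribution]:
    """Standard PSA distribution set.

    Beta for every probability parameter (complication occurrence,
    case-fatality, per-cycle control probabilities), gamma for every cost
    parameter (complication and general care costs, unit test costs,
    device cost), all centred on the base case with ``sd = dispersion *
    mean``.  Parameters with a base value of zero are kept fixed.
    """
    dists = []
    for path in _table_parameter_paths(config):
        mean = get_param(config, path)
        is_cost = "cost" in path
        family = "gamma" if is_cost else "beta"
        if mean == 0.0:
            family = "fixed"
        dists.append(
            ParamDistribution(
                parameter_path=path, family=family, mean=mean,
                dispersion=dispersion,
            )
        )
    for strat in config.strategies:
        for fld, family in (
            ("control_prob_per_cycle", "beta"),
            ("test_cost_per_test", "gamma"),
            ("device_cost", "gamma"),
        ):
            mean = getattr(strat, fld)
            dists.append(
                ParamDistribution(
                    parameter_path=f"strategies.{strat.name}.{fld}",
                    family="fixed" if mean == 0.0 else family,
                    mean=mean,
                    dispersion=dispersion,
                )
            )
    return dists


def default_tornado_ranges(
    config: ModelConfig, relative_range: float = 0.2
) -> list[tuple[str, float, float]]:
    """±20% one-way ranges over the literature parameter ledger."""
    ranges = []
    for path in _table_parameter_paths(config):
        base = get_param(config, path)
        ranges.append(
            (path, base * (1.0 - relative_range), base * (1.0 + relative_range))
        )
    return ranges


def _sample(
    dist: ParamDistribution, rng: np.random.Generator, n: int
) -> np.ndarray:
    mean = dist.mean
    sd = dist.dispersion * mean
    if dist.family == "fixed" or sd == 0.0:
        draws = np.full(n, mean)
    elif dist.family == "beta":
        nu = mean * (1.0 - mean) / sd**2 - 1.0
        if nu <= 0:
            raise ConfigurationError(
                f"psa.{dist.parameter_path}: beta moments infeasible"
            )
        draws = rng.beta(mean * nu, (1.0 - mean) * nu, size=n)
    elif dist.family == "gamma":
        shape = (mean / sd) ** 2
        draws = rng.gamma(shape, sd**2 / mean, size=n)
    elif dist.family == "uniform":
        if dist.bounds is not None:
            low, high = dist.bounds
        else:
            half = np.sqrt(3.0) * sd
            low, high = mean - half, mean + half
        draws = rng.uniform(low, high, size=n)
    else:  # pragma: no cover - blocked by ParamDistribution validation
        raise ConfigurationError(f"unknown family {dist.family!r}")
    if dist.bounds is not None and dist.family != "uniform":
        draws = np.clip(draws, dist.bounds[0], dist.bounds[1])
    return draws


@dataclass(frozen=True)
class PSAResult:
    """Monte Carlo trial outcomes and summaries.

    ``per_trial`` has one row per trial with cost/effectiveness per
    strategy plus the incremental pair; ``percentile_summary`` holds the
    2.5th/97.5th percentiles per quantity; ``ce_plane`` the
    (delta_effect, delta_cost) scatter; ``nmb_acceptance`` the fraction of
    trials with positive incremental NMB per WTP value.
    """

    n_trials: int
    seed: int
    per_trial: pd.DataFrame
    percentile_summary: pd.DataFrame
    ce_plane: pd.DataFrame
    nmb_acceptance: pd.DataFrame
    strategies: tuple[str, str] = field(default=("poc", "lab"))


def run_psa(
    config: ModelConfig,
    distributions: list[ParamDistribution],
    n_trials: int,
    seed: int,
    wtp_grid: np.ndarray | list[float] | None = None,
) -> PSAResult:
    """Monte Carlo probabilistic sensitivity analysis.

    Each trial samples every distribution independently, writes the draws
    into a copy of the configuration, and re-evaluates both strategies.
    Results are reproducible for a fixed ``seed``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if wtp_grid is None:
        wtp_grid = DEFAULT_WTP_GRID
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    rng = np.random.default_rng(seed)
    draws = np.column_stack(
        [_sample(dist, rng, n_trials) for dist in distributions]
    ) if distributions else np.empty((n_trials, 0))

    first, second = config.strategies[0].name, config.strategies[1].name
    rows = []
    for trial in range(n_trials):
        trial_config = config.copy()
        for j, dist in enumerate(distributions):
            set_param(trial_config, dist.parameter_path, float(draws[trial, j]))
        outcomes = {o.strategy: o for o in evaluate_strategies(trial_config)}
        comp = compare(outcomes[first], outcomes[second])
        rows.append(
            {
                "trial": trial,
                f"cost_{first}": outcomes[first].discounted_cost,
                f"eff_{first}": outcomes[first].effectiveness,
                f"cost_{second}": outcomes[second].discounted_cost,
                f"eff_{second}": outcomes[second].effectiveness,
                "delta_cost": comp.delta_cost,
                "delta_effect": comp.delta_effect,
            }
        )
    per_trial = pd.DataFrame(rows)

    quantities = [c for c in per_trial.columns if c != "trial"]
    percentile_summary = pd.DataFrame(
        {
            "quantity": quantities,
            "p2.5": [np.percentile(per_trial[q], 2.5) for q in quantities],
            "p97.5": [np.percentile(per_trial[q], 97.5) for q in quantities],
        }
    )
    ce_plane = per_trial[["delta_effect", "delta_cost"]].copy()
    inc_nmb = (
        wtp_grid[None, :] * per_trial["delta_effect"].to_numpy()[:, None]
        - per_trial["delta_cost"].to_numpy()[:, None]
    )
    nmb_acceptance = pd.DataFrame(
        {"wtp": wtp_grid, "p_positive_incremental_nmb": (inc_nmb > 0).mean(axis=0)}
    )
    return PSAResult(
        n_trials=n_trials,
        seed=seed,
        per_trial=per_trial,
        percentile_summary=percentile_summary,
        ce_plane=ce_plane,
        nmb_acceptance=nmb_acceptance,
        strategies=(first, second),
    )


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity result for a single parameter."""

    parameter_path: str
    low_input: float
    high_input: float
    outcome_low: float
    outcome_high: float

    @property
    def width(self) -> float:
        return abs(self.outcome_high - self.outcome_low)


def _incremental_nmb(config: ModelConfig, wtp: float) -> float:
    outcomes = evaluate_strategies(config)
    comp = compare(outcomes[0], outcomes[1])
    return wtp * comp.delta_effect - comp.delta_cost


def tornado(
    config: ModelConfig,
    parameter_ranges: list[tuple[str, float, float]],
    wtp: float,
) -> list[TornadoEntry]:
    """One-way sensitivity on incremental NMB, ranked by descending width.

    Each parameter is swept to its low and high value with every other
    parameter held at base case.  Ordering is independent of the order in
    which parameters are supplied (ties broken alphabetically).
    """
    if wtp < 0:
        raise ValueError("wtp must be >= 0")
    entries = []
    for path, low, high in parameter_ranges:
        if low > high:
            raise ValueError(f"{path}: low {low} > high {high}")
        get_param(config, path)  # validate the path before sweeping
        outs = []
        for value in (low, high):
            swept = config.copy()
            set_param(swept, path, value)
            outs.append(_incremental_nmb(swept, wtp))
        entries.append(
            TornadoEntry(
                parameter_path=path,
                low_input=low,
                high_input=high,
                outcome_low=outs[0],
                outcome_high=outs[1],
            )
        )
    return sorted(entries, key=lambda e: (-e.width, e.parameter_path))


def tornado_frame(entries: list[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(entries) + 1),
            "parameter": [e.parameter_path for e in entries],
            "low_input": [e.low_input for e in entries],
            "high_input": [e.high_input for e in entries],
            "outcome_low": [e.outcome_low for e in entries],
            "outcome_high": [e.outcome_high for e in entries],
            "width": [e.width for e in entries],
        }
    )
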