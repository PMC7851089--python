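"""Synthetic patient-cohort generator and per-cycle control-rate estimation.

The generator emulates the observed primary-care cohort at patient level:
group sizes, A1c result availability, sex, age, hypertension, a
right-skewed baseline A1c distribution matched to the reported median and
interquartile range, and time-to-control simulated as a constant per-cycle
Bernoulli hazard over the follow-up window.  Patients without an available
A1c result cannot be assessed and never register control.

From a generated (or imported) cohort, :func:`estimate_control_rate`
recovers the per-cycle probability of reaching the glycemic target — the
key strategy parameter of the Markov model — by maximum likelihood under a
constant-hazard discrete-time model with censoring at follow-up end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .config import CohortConfig, ConfigurationError

__all__ = [
    "PatientRecord",
    "SyntheticCohort",
    "ControlRateEstimate",
    "fit_lognormal_from_quartiles",
    "generate_cohort",
    "estimate_control_rate",
    "summarize_baseline",
]

GROUPS = ("poc", "lab")
CSV_COLUMNS = (
    "id",
    "group",
    "sex",
    "age",
    "hypertension",
    "baseline_a1c",
    "controlled_at_cycle",
)

_Z75 = norm.ppf(0.75)  # 0.6744897...

# plausible physiologic range for glycated hemoglobin (%); draws are clipped
_A1C_MIN, _A1C_MAX = 4.0, 19.9


class EstimationError(ValueError):
    """Raised when an estimator is given an empty or degenerate group."""


@dataclass(frozen=True)
class PatientRecord:
    """One simulated patient."""

    id: str
    group: str
    sex: str
    age: float
    hypertension: bool
    baseline_a1c: float | None
    controlled_at_cycle: int | None


@dataclass(frozen=True)
class SyntheticCohort:
    """Generated patient-level data plus the configuration that produced it.

    ``data`` is a DataFrame with columns :data:`CSV_COLUMNS`;
    ``baseline_a1c`` and ``controlled_at_cycle`` are NaN when missing.
    """

    data: pd.DataFrame
    config: CohortConfig

    @property
    def patients(self) -> list[PatientRecord]:
        records = []
        for row in self.data.itertuples(index=False):
            records.append(
                PatientRecord(
                    id=row.id,
                    group=row.group,
                    sex=row.sex,
                    age=float(row.age),
                    hypertension=bool(row.hypertension),
                    baseline_a1c=None
                    if pd.isna(row.baseline_a1c)
                    else float(row.baseline_a1c),
                    controlled_at_cycle=None
                    if pd.isna(row.controlled_at_cycle)
                    else int(row.controlled_at_cycle),
                )
            )
        return records

    def group_data(self, group: str) -> pd.DataFrame:
        if group not in GROUPS:
            raise ConfigurationError(f"group must be one of {GROUPS}, got {group!r}")
        return self.data[self.data["group"] == group]

    def to_csv(self, path: str | Path) -> None:
        out = self.data.copy()
        out["hypertension"] = out["hypertension"].astype(int)
        out["controlled_at_cycle"] = out["controlled_at_cycle"].astype("Int64")
        out.to_csv(path, index=False, columns=list(CSV_COLUMNS))

    @classmethod
    def from_csv(cls, path: str | Path, config: CohortConfig) -> "SyntheticCohort":
        data = pd.read_csv(path, dtype={"id": str})
        missing = set(CSV_COLUMNS) - set(data.columns)
        if missing:
            raise ConfigurationError(f"cohort CSV missing columns {sorted(missing)}")
        data["hypertension"] = data["hypertension"].astype(bool)
        return cls(data=data[list(CSV_COLUMNS)], config=config)


@dataclass(frozen=True)
class ControlRateEstimate:
    """Maximum-likelihood per-cycle control probability with a 95% CI."""

    group: str
    p_hat: float
    ci_low: float
    ci_high: float
    n_used: int
    n_events: int
    person_cycles: int


def fit_lognormal_from_quartiles(
    median: float, q25: float, q75: float
) -> tuple[float, float]:
    """Log-normal (mu, sigma) matching the median exactly and the quartiles
    in least squares.

    ``mu = log(median)``; ``sigma`` minimizes the squared distance of the
    implied 25th/75th percentiles from the targets.
    """
    if not 0 < q25 < median < q75:
        raise ValueError("requires 0 < q25 < median < q75")
    mu = np.log(median)

    def loss(sigma: float) -> float:
        lo = np.exp(mu - _Z75 * sigma)
        hi = np.exp(mu + _Z75 * sigma)
        return (lo - q25) ** 2 + (hi - q75) ** 2

    res = minimize_scalar(loss, bounds=(1e-6, 2.0), method="bounded")
    return mu, float(res.x)


def _first_success_cycle(
    rng: np.random.Generator, n: int, p: float, k: int
) -> np.ndarray:
    """First cycle (1-based) of success in k Bernoulli(p) trials; NaN if none."""
    draws = rng.random((n, k)) < p
    any_success = draws.any(axis=1)
    first = draws.argmax(axis=1) + 1.0
    return np.where(any_success, first, np.nan)


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Draw a synthetic patient-level cohort; bit-reproducible per seed."""
    rng = np.random.default_rng(config.seed)
    frames = []
    for group in GROUPS:
        g = config.group(group)
        n = g["n"]
        available = rng.random(n) < g["p_available"]
        male = rng.random(n) < g["p_male"]
        age = rng.normal(g["age_mean"], g["age_sd"], size=n)
        hypertension = rng.random(n) < g["p_hypertension"]
        mu, sigma = fit_lognormal_from_quartiles(
            g["a1c_median"], g["a1c_iqr"][0], g["a1c_iqr"][1]
        )
        a1c = np.clip(rng.lognormal(mu, sigma, size=n), _A1C_MIN, _A1C_MAX)
        a1c = np.where(available, a1c, np.nan)
        controlled = _first_success_cycle(
            rng, n, g["control_prob"], config.followup_cycles
        )
        # without an available result, control is never ascertained
        controlled = np.where(available, controlled, np.nan)
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{group}-{i:05d}" for i in range(n)],
                    "group": group,
                    "sex": np.where(male, "male", "female"),
                    "age": age,
                    "hypertension": hypertension,
                    "baseline_a1c": a1c,
                    "controlled_at_cycle": controlled,
                }
            )
        )
    data = pd.concat(frames, ignore_index=True)
    return SyntheticCohort(data=data, config=config)


def estimate_control_rate(cohort: SyntheticCohort, group: str) -> ControlRateEstimate:
    """MLE of the per-cycle control probability for one group.

    Under a constant discrete-time hazard, each person-cycle at risk is an
    independent Bernoulli trial, so ``p_hat = events / person-cycles`` with
    a Wilson score interval.  Only patients with an available A1c result
    (assessable patients) contribute.
    """
    data = cohort.group_data(group)
    assessable = data[data["baseline_a1c"].notna()]
    if assessable.empty:
        raise EstimationError(f"group {group!r}: no assessable patients")
    k = cohort.config.followup_cycles
    ctrl = assessable["controlled_at_cycle"]
    events = int(ctrl.notna().sum())
    person_cycles = int(ctrl.fillna(k).sum())
    p_hat = events / person_cycles
    ci_low, ci_high = proportion_confint(
        events, person_cycles, alpha=0.05, method="wilson"
    )
    return ControlRateEstimate(
        group=group,
        p_hat=float(p_hat),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        n_used=int(len(assessable)),
        n_events=events,
        person_cycles=person_cycles,
    )


def summarize_baseline(cohort: SyntheticCohort) -> pd.DataFrame:
    """Per-group baseline characteristics table (one row per group)."""
    if cohort.data.empty:
        raise EstimationError("empty cohort")
    rows = []
    for group in GROUPS:
        data = cohort.group_data(group)
        if data.empty:
            continue
        with_a1c = data["baseline_a1c"].notna()
        rows.append(
            {
                "group": group,
                "n": len(data),
                "n_a1c_available": int(with_a1c.sum()),
                "frac_a1c_available": float(with_a1c.mean()),
                "frac_male": float((data["sex"] == "male").mean()),
                "age_mean": float(data["age"].mean()),
                "age_sd": float(data["age"].std(ddof=1)) if len(data) > 1 else 0.0,
                "a1c_median": float(data["baseline_a1c"].median()),
                "a1c_q25": float(data["baseline_a1c"].quantile(0.25)),
                "a1c_q75": float(data["baseline_a1c"].quantile(0.75)),
                "frac_hypertension": float(data["hypertension"].mean()),
                "frac_ever_controlled": float(
                    data["controlled_at_cycle"].notna().mean()
                ),
            }
        )
    return pd.DataFrame(rows)
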