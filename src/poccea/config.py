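"""Parameter ledger of the decision problem and configuration file I/O.

A single YAML (or JSON) file with sections ``model``, ``strategies``,
``cohort``, ``psa`` and ``tornado`` describes one complete analysis.  The
packaged ``reference_config`` reproduces the published parameterization:
quarterly cycles over ten years, 4% annual discounting with half-cycle
correction, the complication cost/probability table, per-cycle glycemic
control probabilities of 0.14 (point-of-care) and 0.0738 (central
laboratory), and unit test costs of US$8.48 + amortized device vs US$2.65.
"""

from __future__ import annotations

import copy
import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any

import yaml

from .states import (
    COMPLICATIONS,
    CONTROLLED,
    DEAD,
    DIABETIC_FOOT,
    DIABETIC_FOOT_SUBCOSTS,
    HOSPITALIZATION,
    STATE_NAMES,
    UNCONTROLLED,
    StateSpec,
    diabetic_foot_cost,
)

EFFECTIVENESS_DEFINITIONS = (
    "at_eval_point",
    "cumulative_ever",
    "discounted_time_in_control",
    "access_adjusted_attainment",
)

DISTRIBUTION_FAMILIES = ("beta", "gamma", "uniform", "fixed")


class ConfigurationError(ValueError):
    """A configuration value violates its constraint; names the offending key."""


def _check_prob(value: float, key: str) -> float:
    if not 0.0 <= value <= 1.0:
        raise ConfigurationError(
            f"{key}={value!r}: probability must be in [0, 1]"
        )
    return float(value)


def _check_nonneg(value: float, key: str) -> float:
    if value < 0:
        raise ConfigurationError(f"{key}={value!r}: must be >= 0")
    return float(value)


def _check_pos(value: float, key: str) -> float:
    if value <= 0:
        raise ConfigurationError(f"{key}={value!r}: must be > 0")
    return float(value)


@dataclass
class StrategySpec:
    """One monitoring strategy (testing modality) under comparison.

    ``control_prob_per_cycle`` is the probability that an uncontrolled
    patient reaches the A1c target in one 3-month cycle.  ``device_cost``
    is amortized over ``device_tests_lifetime`` tests and added to each
    test.  ``p_result_available`` is the fraction of patients with an A1c
    result actually available under the strategy; it scales the
    access-adjusted effectiveness endpoint.
    """

    name: str
    control_prob_per_cycle: float
    test_cost_per_test: float
    device_cost: float = 0.0
    device_tests_lifetime: int = 5000
    tests_per_cycle: float = 1.0
    p_result_available: float = 1.0

    def __post_init__(self) -> None:
        pfx = f"strategies.{self.name}"
        _check_prob(self.control_prob_per_cycle, f"{pfx}.control_prob_per_cycle")
        _check_nonneg(self.test_cost_per_test, f"{pfx}.test_cost_per_test")
        _check_nonneg(self.device_cost, f"{pfx}.device_cost")
        if self.device_cost > 0 and self.device_tests_lifetime <= 0:
            raise ConfigurationError(
                f"{pfx}.device_tests_lifetime must be > 0 when device_cost > 0"
            )
        _check_nonneg(self.tests_per_cycle, f"{pfx}.tests_per_cycle")
        _check_prob(self.p_result_available, f"{pfx}.p_result_available")

    @property
    def cost_per_test(self) -> float:
        """Unit test cost including the amortized device share."""
        amortized = (
            self.device_cost / self.device_tests_lifetime
            if self.device_cost > 0
            else 0.0
        )
        return self.test_cost_per_test + amortized


@dataclass
class ModelConfig:
    """Full parameter set of the Markov cohort model."""

    cycle_length_months: float = 3.0
    horizon_years: float = 10.0
    annual_discount_rate: float = 0.04
    half_cycle_correction: bool = True
    target_a1c: float = 7.5
    effectiveness_definition: str = "cumulative_ever"
    effectiveness_eval_cycles: int = 2
    general_annual_cost: float = 1844.00
    occurrence_probs_annual: dict[str, float] = field(default_factory=dict)
    complication_risk_rr_controlled: float = 0.0
    relapse_prob_per_cycle: float = 0.0
    background_death_prob_annual: float = 0.0
    hospitalization_resolves: bool = True
    state_specs: list[StateSpec] = field(default_factory=list)
    strategies: list[StrategySpec] = field(default_factory=list)

    def __post_init__(self) -> None:
        _check_pos(self.cycle_length_months, "model.cycle_length_months")
        _check_pos(self.horizon_years, "model.horizon_years")
        _check_nonneg(self.annual_discount_rate, "model.annual_discount_rate")
        n = self.horizon_years * 12.0 / self.cycle_length_months
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "model.horizon_years*12/cycle_length_months "
                f"= {n} is not an integer cycle count"
            )
        if self.effectiveness_definition not in EFFECTIVENESS_DEFINITIONS:
            raise ConfigurationError(
                f"model.effectiveness_definition={self.effectiveness_definition!r}: "
                f"must be one of {EFFECTIVENESS_DEFINITIONS}"
            )
        if not 1 <= self.effectiveness_eval_cycles <= round(n):
            raise ConfigurationError(
                "model.effectiveness_eval_cycles must be in "
                f"[1, {round(n)}], got {self.effectiveness_eval_cycles}"
            )
        _check_nonneg(self.general_annual_cost, "model.general_annual_cost")
        for state, p in self.occurrence_probs_annual.items():
            if state not in COMPLICATIONS:
                raise ConfigurationError(
                    f"model.occurrence_probs_annual.{state}: unknown complication"
                )
            _check_prob(p, f"model.occurrence_probs_annual.{state}")
        _check_prob(
            self.complication_risk_rr_controlled,
            "model.complication_risk_rr_controlled",
        )
        _check_prob(self.relapse_prob_per_cycle, "model.relapse_prob_per_cycle")
        _check_prob(
            self.background_death_prob_annual,
            "model.background_death_prob_annual",
        )
        names = [s.state for s in self.state_specs]
        if len(names) != len(set(names)):
            raise ConfigurationError("model.states: duplicate state spec")
        snames = [s.name for s in self.strategies]
        if len(snames) != len(set(snames)):
            raise ConfigurationError("strategies: duplicate strategy name")

    # -- lookups ---------------------------------------------------------

    @property
    def n_cycles(self) -> int:
        return round(self.horizon_years * 12.0 / self.cycle_length_months)

    @property
    def cycle_length_years(self) -> float:
        return self.cycle_length_months / 12.0

    def state_spec(self, state: str) -> StateSpec:
        for spec in self.state_specs:
            if spec.state == state:
                return spec
        return StateSpec(state=state)

    def strategy(self, name: str) -> StrategySpec:
        for s in self.strategies:
            if s.name == name:
                return s
        raise ConfigurationError(f"strategies.{name}: no such strategy")

    def copy(self) -> "ModelConfig":
        return copy.deepcopy(self)


@dataclass
class CohortConfig:
    """Parameters of the synthetic patient-cohort generator.

    Defaults emulate the observed primary-care cohort: 288 patients in the
    unit with the point-of-care device vs 1,102 in the comparison units,
    A1c result availability 76% vs 36%, and the published baseline age,
    sex, hypertension and A1c distributions over an 18-month (6-cycle)
    follow-up.
    """

    n_poc: int = 288
    n_lab: int = 1102
    p_a1c_available_poc: float = 0.76
    p_a1c_available_lab: float = 0.36
    p_male_poc: float = 0.37
    p_male_lab: float = 0.234
    age_mean_poc: float = 61.9
    age_mean_lab: float = 56.8
    # reported age dispersions (0.91, 0.55) are standard errors of the mean;
    # the generator uses SD = SE * sqrt(n)
    age_sd_poc: float = 15.44
    age_sd_lab: float = 18.26
    a1c_median_poc: float = 7.8
    a1c_iqr_poc: tuple[float, float] = (6.7, 9.5)
    a1c_median_lab: float = 7.9
    a1c_iqr_lab: tuple[float, float] = (6.8, 10.6)
    p_hypertension_poc: float = 0.917
    p_hypertension_lab: float = 0.935
    control_prob_per_cycle_poc: float = 0.14
    control_prob_per_cycle_lab: float = 0.0738
    followup_cycles: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        for key in ("n_poc", "n_lab"):
            if getattr(self, key) <= 0:
                raise ConfigurationError(f"cohort.{key} must be > 0")
        for key in (
            "p_a1c_available_poc",
            "p_a1c_available_lab",
            "p_male_poc",
            "p_male_lab",
            "p_hypertension_poc",
            "p_hypertension_lab",
            "control_prob_per_cycle_poc",
            "control_prob_per_cycle_lab",
        ):
            _check_prob(getattr(self, key), f"cohort.{key}")
        for grp in ("poc", "lab"):
            lo, hi = getattr(self, f"a1c_iqr_{grp}")
            med = getattr(self, f"a1c_median_{grp}")
            if not lo < med < hi:
                raise ConfigurationError(
                    f"cohort.a1c_iqr_{grp}={lo, hi!r}: requires "
                    f"IQR lower < median ({med}) < IQR upper"
                )
        if self.followup_cycles < 1:
            raise ConfigurationError("cohort.followup_cycles must be >= 1")

    def group(self, name: str) -> dict[str, Any]:
        """Per-group parameter view (``poc`` or ``lab``)."""
        if name not in ("poc", "lab"):
            raise ConfigurationError(f"cohort group must be poc or lab, got {name!r}")
        return {
            "n": getattr(self, f"n_{name}"),
            "p_available": getattr(self, f"p_a1c_available_{name}"),
            "p_male": getattr(self, f"p_male_{name}"),
            "age_mean": getattr(self, f"age_mean_{name}"),
            "age_sd": getattr(self, f"age_sd_{name}"),
            "a1c_median": getattr(self, f"a1c_median_{name}"),
            "a1c_iqr": tuple(getattr(self, f"a1c_iqr_{name}")),
            "p_hypertension": getattr(self, f"p_hypertension_{name}"),
            "control_prob": getattr(self, f"control_prob_per_cycle_{name}"),
        }


@dataclass
class ParamDistribution:
    """Sampling distribution of one model parameter for the PSA.

    ``parameter_path`` is a dotted reference into the configuration, e.g.
    ``model.states.nephropathy.annual_cost`` or
    ``strategies.poc.control_prob_per_cycle``.  Beta and gamma are
    parameterized by method of moments from ``mean`` and
    ``sd = dispersion * mean``.
    """

    parameter_path: str
    family: str
    mean: float
    dispersion: float = 0.2
    bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.family not in DISTRIBUTION_FAMILIES:
            raise ConfigurationError(
                f"psa.{self.parameter_path}.family={self.family!r}: "
                f"must be one of {DISTRIBUTION_FAMILIES}"
            )
        if self.family == "beta":
            _check_prob(self.mean, f"psa.{self.parameter_path}.mean")
            sd = self.dispersion * self.mean
            if self.mean > 0 and sd**2 >= self.mean * (1 - self.mean):
                raise ConfigurationError(
                    f"psa.{self.parameter_path}: beta moments infeasible "
                    f"(sd^2 >= mean*(1-mean))"
                )
        elif self.family == "gamma":
            _check_nonneg(self.mean, f"psa.{self.parameter_path}.mean")
        elif self.family == "uniform" and self.bounds is None:
            _check_nonneg(self.dispersion, f"psa.{self.parameter_path}.dispersion")


# ---------------------------------------------------------------------------
# parameter-path resolution (used by PSA and tornado)
# ---------------------------------------------------------------------------


def get_param(config: ModelConfig, path: str) -> float:
    """Read the parameter at a dotted ``path`` from the configuration."""
    return _resolve(config, path)[1]


def set_param(config: ModelConfig, path: str, value: float) -> None:
    """Set the parameter at a dotted ``path`` in place."""
    setter = _resolve(config, path)[0]
    setter(value)


def _resolve(config: ModelConfig, path: str):
    parts = path.split(".")
    try:
        if parts[0] == "model":
            if parts[1] == "occurrence_probs_annual":
                state = parts[2]
                cur = config.occurrence_probs_annual[state]
                return (
                    lambda v: config.occurrence_probs_annual.__setitem__(state, v),
                    cur,
                )
            if parts[1] == "states":
                state, fld = parts[2], parts[3]
                spec = config.state_spec(state)
                if spec not in config.state_specs:
                    raise KeyError(state)
                idx = config.state_specs.index(spec)

                def set_state(v, idx=idx, fld=fld):
                    config.state_specs[idx] = dataclasses.replace(
                        config.state_specs[idx], **{fld: v}
                    )

                return set_state, getattr(spec, fld)
            fld = parts[1]
            cur = getattr(config, fld)
            if not isinstance(cur, (int, float)) or isinstance(cur, bool):
                raise KeyError(fld)
            return lambda v: setattr(config, fld, v), cur
        if parts[0] == "strategies":
            strat = config.strategy(parts[1])
            cur = getattr(strat, parts[2])
            return lambda v: setattr(strat, parts[2], v), cur
    except (AttributeError, IndexError, KeyError) as exc:
        raise ConfigurationError(f"unknown parameter path {path!r}") from exc
    raise ConfigurationError(f"unknown parameter path {path!r}")


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MODEL_FIELDS = {f.name for f in dataclasses.fields(ModelConfig)} - {
    "state_specs",
    "strategies",
}


def _states_from_mapping(raw: dict[str, Any]) -> list[StateSpec]:
    specs = []
    for state, entry in raw.items():
        if state not in STATE_NAMES:
            raise ConfigurationError(f"model.states.{state}: unknown state")
        entry = dict(entry)
        components = entry.pop("annual_cost_components", None)
        if components is not None:
            entry["annual_cost"] = sum(components) / len(components)
        unknown = set(entry) - {
            "annual_cost",
            "death_prob_annual",
            "chronic",
            "accrues_general_cost",
        }
        if unknown:
            raise ConfigurationError(
                f"model.states.{state}: unknown keys {sorted(unknown)}"
            )
        specs.append(StateSpec(state=state, **entry))
    return specs


def config_from_mapping(raw: dict[str, Any]) -> dict[str, Any]:
    """Build configuration objects from a parsed YAML/JSON mapping.

    Returns a dict with keys ``model`` (:class:`ModelConfig`), ``cohort``
    (:class:`CohortConfig`), ``psa`` and ``tornado`` (raw option mappings
    consumed by :mod:`poccea.sensitivity`).
    """
    model_raw = dict(raw.get("model", {}))
    states_raw = model_raw.pop("states", {})
    unknown = set(model_raw) - _MODEL_FIELDS
    if unknown:
        raise ConfigurationError(f"model: unknown keys {sorted(unknown)}")
    strategies = [
        StrategySpec(**entry) for entry in raw.get("strategies", [])
    ]
    model = ModelConfig(
        state_specs=_states_from_mapping(states_raw),
        strategies=strategies,
        **model_raw,
    )
    cohort_raw = dict(raw.get("cohort", {}))
    for key in ("a1c_iqr_poc", "a1c_iqr_lab"):
        if key in cohort_raw:
            cohort_raw[key] = tuple(cohort_raw[key])
    unknown = set(cohort_raw) - {f.name for f in dataclasses.fields(CohortConfig)}
    if unknown:
        raise ConfigurationError(f"cohort: unknown keys {sorted(unknown)}")
    cohort = CohortConfig(**cohort_raw)
    return {
        "model": model,
        "cohort": cohort,
        "psa": dict(raw.get("psa", {})),
        "tornado": dict(raw.get("tornado", {})),
    }


def load_config(path: str | Path) -> dict[str, Any]:
    """Load and validate a YAML or JSON configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"configuration file not found: {path}")
    text = path.read_text()
    if path.suffix == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping at top level")
    return config_from_mapping(raw)


def config_to_mapping(model: ModelConfig, cohort: CohortConfig | None = None,
                      psa: dict | None = None, tornado: dict | None = None) -> dict:
    """Serialize configuration objects back to a plain mapping."""
    model_map = {
        f: getattr(model, f) for f in sorted(_MODEL_FIELDS)
    }
    model_map["states"] = {
        s.state: {
            "annual_cost": s.annual_cost,
            "death_prob_annual": s.death_prob_annual,
            "chronic": s.chronic,
            "accrues_general_cost": s.accrues_general_cost,
        }
        for s in model.state_specs
    }
    out: dict[str, Any] = {
        "model": model_map,
        "strategies": [dataclasses.asdict(s) for s in model.strategies],
    }
    if cohort is not None:
        cmap = dataclasses.asdict(cohort)
        cmap["a1c_iqr_poc"] = list(cmap["a1c_iqr_poc"])
        cmap["a1c_iqr_lab"] = list(cmap["a1c_iqr_lab"])
        out["cohort"] = cmap
    if psa:
        out["psa"] = psa
    if tornado:
        out["tornado"] = tornado
    return out


def save_config(path: str | Path, model: ModelConfig,
                cohort: CohortConfig | None = None,
                psa: dict | None = None, tornado: dict | None = None) -> None:
    path = Path(path)
    mapping = config_to_mapping(model, cohort, psa, tornado)
    if path.suffix == ".json":
        path.write_text(json.dumps(mapping, indent=2))
    else:
        path.write_text(yaml.safe_dump(mapping, sort_keys=False))


def reference_config_path() -> Path:
    """Path of the packaged reference configuration file."""
    return Path(resources.files("poccea").joinpath("data/reference_config.yaml"))


def reference_config() -> dict[str, Any]:
    """The packaged reference parameterization of the published analysis."""
    return load_config(reference_config_path())
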