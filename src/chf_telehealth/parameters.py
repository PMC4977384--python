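"""Model parameters: transition hazards, program efficacy, costs, cohorts.

All inputs of the model are small tables of probabilities and dollar
amounts.  They are held in frozen dataclasses that validate themselves on
construction, so that every downstream computation can assume well-formed
values.  :func:`builtin_defaults` returns the published base-case
parameterization; :func:`load_config` reads a YAML/JSON configuration that
may override any subset of it.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

logger = logging.getLogger("chf_telehealth")

#: Order of model states.  The five living states count prior CHF
#: hospital admissions; ``death`` is absorbing.
STATES = ("H0", "H1", "H2", "H3", "H4plus", "death")
LIVING_STATES = STATES[:-1]

NYHA_II_III = "NYHA II or III"
NYHA_III_IV = "NYHA III or IV"


class ConfigError(ValueError):
    """A configuration file could not be parsed or names an unknown key."""


class ParameterError(ValueError):
    """A parameter value violates a model constraint."""


def _check_prob(value: float, name: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise ParameterError(f"{name} must be a probability in [0, 1], got {value!r}")
    return value


def _check_nonneg(value: float, name: str) -> float:
    value = float(value)
    if value < 0 or math.isnan(value):
        raise ParameterError(f"{name} must be >= 0, got {value!r}")
    return value


@dataclass(frozen=True)
class TransitionParameters:
    """Monthly transition hazards for one NYHA severity stratum.

    ``p_hosp_by_state`` maps each living state (count of prior admissions)
    to the monthly probability of a CHF hospitalization.  Death is resolved
    conditionally on the hospitalization outcome of the cycle:
    ``p_death_hospitalized`` applies given an admission event,
    ``p_death_not_hospitalized`` otherwise.
    """

    p_hosp_by_state: Mapping[str, float]
    p_death_not_hospitalized: float
    p_death_hospitalized: float
    label: str = "custom"

    def __post_init__(self) -> None:
        hosp = dict(self.p_hosp_by_state)
        if set(hosp) != set(LIVING_STATES):
            raise ParameterError(
                "p_hosp_by_state must be defined for exactly the living states "
                f"{LIVING_STATES}, got {sorted(hosp)}"
            )
        for state, p in hosp.items():
            hosp[state] = _check_prob(p, f"p_hosp_by_state[{state}]")
        object.__setattr__(self, "p_hosp_by_state", hosp)
        object.__setattr__(
            self,
            "p_death_not_hospitalized",
            _check_prob(self.p_death_not_hospitalized, "p_death_not_hospitalized"),
        )
        object.__setattr__(
            self,
            "p_death_hospitalized",
            _check_prob(self.p_death_hospitalized, "p_death_hospitalized"),
        )

    def hosp_array(self):
        import numpy as np

        return np.array([self.p_hosp_by_state[s] for s in LIVING_STATES])

    def validate_monotone(self) -> None:
        """Check that hospitalization risk is nondecreasing in prior admissions.

        This holds for both built-in hazard columns; it is checked for them
        at package load but merely available for user configurations, where
        a non-monotone table is legal.
        """
        values = [self.p_hosp_by_state[s] for s in LIVING_STATES]
        if any(b < a for a, b in zip(values, values[1:])):
            raise ParameterError(
                f"p_hosp_by_state not nondecreasing in prior admissions: {values}"
            )


@dataclass(frozen=True)
class EfficacyScenario:
    """Telehealth program performance bundle.

    ``sensitivity``/``specificity`` describe the home exacerbation
    detection test; the three reduction fractions are the proportional
    effects on mortality hazard, hospitalization hazard and hospital
    length of stay attributed to the program.
    """

    sensitivity: float
    specificity: float
    mortality_reduction: float
    hospitalization_reduction: float
    los_reduction: float
    label: str = "custom"

    def __post_init__(self) -> None:
        for name in (
            "sensitivity",
            "specificity",
            "mortality_reduction",
            "hospitalization_reduction",
            "los_reduction",
        ):
            object.__setattr__(self, name, _check_prob(getattr(self, name), name))

    @classmethod
    def null(cls) -> "EfficacyScenario":
        """A program with no clinical effect and a test that never fires."""
        return cls(0.0, 1.0, 0.0, 0.0, 0.0, label="null")


@dataclass(frozen=True)
class CostSchedule:
    """All dollar parameters (2013 USD) plus the annual discount rate."""

    cost_per_admission: float = 12_000.0
    annual_chf_outpatient: float = 1_700.0
    annual_non_chf: float = 10_000.0
    monthly_install: float = 15.0
    monthly_monitoring: float = 80.0
    monthly_case_manager: float = 125.0
    treat_physician: float = 52.0
    treat_nurse_visit: float = 135.0
    annual_discount_rate: float = 0.03

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            object.__setattr__(
                self, f.name, _check_nonneg(getattr(self, f.name), f.name)
            )

    @property
    def monthly_test(self) -> float:
        """Recurring monitoring (TEST) cost per telehealth patient-month."""
        return self.monthly_install + self.monthly_monitoring + self.monthly_case_manager

    @property
    def treat_per_episode(self) -> float:
        """Early-intervention (TREAT) cost per positive detection."""
        return self.treat_physician + self.treat_nurse_visit

    def with_monthly_test(self, fee: float) -> "CostSchedule":
        """Replace the whole TEST bundle by a single monthly fee."""
        return dataclasses.replace(
            self, monthly_install=0.0, monthly_monitoring=0.0, monthly_case_manager=fee
        )


@dataclass(frozen=True)
class CohortSpec:
    """Initial state distribution, horizon and hazard stratum of a cohort."""

    initial_distribution: Mapping[str, float]
    horizon_months: int = 60
    nyha_label: str = NYHA_II_III
    label: str = "custom"

    def __post_init__(self) -> None:
        dist = {s: 0.0 for s in STATES}
        for state, p in dict(self.initial_distribution).items():
            if state not in STATES:
                raise ParameterError(
                    f"initial_distribution has unknown state {state!r}; "
                    f"valid states are {STATES}"
                )
            dist[state] = _check_prob(p, f"initial_distribution[{state}]")
        total = sum(dist.values())
        if abs(total - 1.0) > 1e-12:
            raise ParameterError(
                f"initial_distribution must sum to 1 (got {total!r})"
            )
        object.__setattr__(self, "initial_distribution", dist)
        if int(self.horizon_months) < 1:
            raise ParameterError(
                f"horizon_months must be a positive integer, got {self.horizon_months!r}"
            )
        object.__setattr__(self, "horizon_months", int(self.horizon_months))

    def mass_array(self):
        import numpy as np

        return np.array([self.initial_distribution[s] for s in STATES])


@dataclass(frozen=True)
class ModelOptions:
    """Conventions of the cohort/economic model that the published tables
    do not state explicitly.  Defaults are the calibrated settings that
    reproduce the published base case; see docs/methods.md.
    """

    #: Scale the mortality/hospitalization reduction fractions by the test
    #: sensitivity (a missed exacerbation cannot avert its admission).
    detection_gated_reductions: bool = True
    #: "all": LOS saving applies to every telehealth admission;
    #: "sen": only to the detected fraction.
    los_gating: str = "all"
    #: Hazard used for the TREAT trigger probability:
    #: "adjusted" (telehealth-arm hazards) or "usual".
    treat_trigger: str = "adjusted"
    #: Credit half a cycle of accrual in the cycle of transition.
    half_cycle: bool = False
    #: Discount life years at the same annual rate as costs.
    discount_life_years: bool = True
    #: Count survivors at cycle "end" or "start" when accruing life years.
    life_year_basis: str = "end"

    def __post_init__(self) -> None:
        if self.los_gating not in ("all", "sen"):
            raise ParameterError(f"los_gating must be 'all' or 'sen', got {self.los_gating!r}")
        if self.treat_trigger not in ("adjusted", "usual"):
            raise ParameterError(
                f"treat_trigger must be 'adjusted' or 'usual', got {self.treat_trigger!r}"
            )
        if self.life_year_basis not in ("start", "end"):
            raise ParameterError(
                f"life_year_basis must be 'start' or 'end', got {self.life_year_basis!r}"
            )


@dataclass(frozen=True)
class ParameterBundle:
    """Everything a run needs: hazards, scenarios, costs, cohorts, options."""

    transitions: Mapping[str, TransitionParameters]
    scenarios: Mapping[str, EfficacyScenario]
    costs: CostSchedule
    cohorts: Mapping[str, CohortSpec]
    options: ModelOptions = field(default_factory=ModelOptions)

    def transition(self, label: str) -> TransitionParameters:
        try:
            return self.transitions[label]
        except KeyError:
            raise KeyError(
                f"unknown transition column {label!r}; available: {sorted(self.transitions)}"
            ) from None


def builtin_defaults() -> ParameterBundle:
    """The published base-case parameterization.

    Two NYHA hazard columns, three efficacy scenarios (best/base/worst),
    the full cost schedule with 3% annual discounting, and the three
    reference cohorts C1 (no prior admissions), C2 (30/30/40% with 1/2/3
    prior admissions) and C3 (4+ prior admissions).
    """
    transitions = {
        NYHA_II_III: TransitionParameters(
            p_hosp_by_state={
                "H0": 0.008, "H1": 0.052, "H2": 0.106, "H3": 0.121, "H4plus": 0.180,
            },
            p_death_not_hospitalized=0.007,
            p_death_hospitalized=0.100,
            label=NYHA_II_III,
        ),
        NYHA_III_IV: TransitionParameters(
            p_hosp_by_state={
                "H0": 0.008, "H1": 0.168, "H2": 0.213, "H3": 0.268, "H4plus": 0.334,
            },
            p_death_not_hospitalized=0.010,
            p_death_hospitalized=0.100,
            label=NYHA_III_IV,
        ),
    }
    for tp in transitions.values():
        tp.validate_monotone()
    scenarios = {
        "best": EfficacyScenario(0.90, 0.90, 0.29, 0.38, 0.30, label="best"),
        "base": EfficacyScenario(0.80, 0.80, 0.24, 0.28, 0.25, label="base"),
        "worst": EfficacyScenario(0.70, 0.70, 0.19, 0.18, 0.20, label="worst"),
    }
    cohorts = {
        "C1": CohortSpec({"H0": 1.0}, 60, NYHA_II_III, label="C1"),
        "C2": CohortSpec({"H1": 0.30, "H2": 0.30, "H3": 0.40}, 60, NYHA_II_III, label="C2"),
        "C3": CohortSpec({"H4plus": 1.0}, 60, NYHA_II_III, label="C3"),
    }
    return ParameterBundle(
        transitions=transitions,
        scenarios=scenarios,
        costs=CostSchedule(),
        cohorts=cohorts,
        options=ModelOptions(),
    )


# ---------------------------------------------------------------------------
# Configuration file I/O
# ---------------------------------------------------------------------------

_COST_FIELDS = {f.name for f in dataclasses.fields(CostSchedule)}
_SCENARIO_FIELDS = {f.name for f in dataclasses.fields(EfficacyScenario)}
_OPTION_FIELDS = {f.name for f in dataclasses.fields(ModelOptions)}


def _parse_transition(label: str, raw: Mapping, base: TransitionParameters | None) -> TransitionParameters:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"transitions[{label!r}] must be a mapping")
    known = {"p_hosp_by_state", "p_death_not_hospitalized", "p_death_hospitalized"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"transitions[{label!r}] has unknown keys {sorted(unknown)}")
    kwargs = dict(
        p_hosp_by_state=dict(base.p_hosp_by_state) if base else None,
        p_death_not_hospitalized=base.p_death_not_hospitalized if base else None,
        p_death_hospitalized=base.p_death_hospitalized if base else None,
    )
    if "p_hosp_by_state" in raw:
        hosp = dict(kwargs["p_hosp_by_state"] or {})
        hosp.update(raw["p_hosp_by_state"])
        kwargs["p_hosp_by_state"] = hosp
    for key in ("p_death_not_hospitalized", "p_death_hospitalized"):
        if key in raw:
            kwargs[key] = raw[key]
    missing = [k for k, v in kwargs.items() if v is None]
    if missing:
        raise ConfigError(f"transitions[{label!r}] missing required keys {missing}")
    return TransitionParameters(label=label, **kwargs)


def _parse_section(label, raw, cls, known, base):
    if not isinstance(raw, Mapping):
        raise ConfigError(f"{label} must be a mapping")
    unknown = set(raw) - known - {"label"}
    if unknown:
        raise ConfigError(f"{label} has unknown keys {sorted(unknown)}")
    kwargs = dataclasses.asdict(base) if base is not None else {}
    kwargs.update(raw)
    try:
        return cls(**kwargs)
    except TypeError as exc:
        raise ConfigError(f"{label}: {exc}") from exc


def load_config(path: str | Path) -> ParameterBundle:
    """Read a YAML (or JSON) configuration file into a validated bundle.

    Any missing section or field falls back to the built-in published
    default; every section-level fallback is logged at INFO level.
    Malformed files raise :class:`ConfigError`; out-of-range values raise
    :class:`ParameterError` naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"configuration file not found: {path}")
    try:
        raw = yaml.safe_load(path.read_text()) or {}
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {path}: {exc}") from exc
    if not isinstance(raw, Mapping):
        raise ConfigError(f"top level of {path} must be a mapping")
    unknown = set(raw) - {"transitions", "scenarios", "costs", "cohorts", "options"}
    if unknown:
        raise ConfigError(f"unknown top-level sections {sorted(unknown)}")

    defaults = builtin_defaults()

    transitions = dict(defaults.transitions)
    if "transitions" in raw:
        for label, spec in (raw["transitions"] or {}).items():
            transitions[label] = _parse_transition(label, spec, transitions.get(label))
    else:
        logger.info("config %s: no 'transitions' section; using built-in hazards", path)

    scenarios = dict(defaults.scenarios)
    if "scenarios" in raw:
        for label, spec in (raw["scenarios"] or {}).items():
            sc = _parse_section(
                f"scenarios[{label!r}]", spec, EfficacyScenario,
                _SCENARIO_FIELDS, scenarios.get(label),
            )
            scenarios[label] = dataclasses.replace(sc, label=label)
    else:
        logger.info("config %s: no 'scenarios' section; using built-in scenarios", path)

    if "costs" in raw:
        costs = _parse_section("costs", raw["costs"], CostSchedule, _COST_FIELDS, defaults.costs)
    else:
        costs = defaults.costs
        logger.info("config %s: no 'costs' section; using built-in cost schedule", path)

    cohorts = dict(defaults.cohorts)
    if "cohorts" in raw:
        for label, spec in (raw["cohorts"] or {}).items():
            if not isinstance(spec, Mapping):
                raise ConfigError(f"cohorts[{label!r}] must be a mapping")
            known = {"initial_distribution", "horizon_months", "nyha_label"}
            unknown = set(spec) - known
            if unknown:
                raise ConfigError(f"cohorts[{label!r}] has unknown keys {sorted(unknown)}")
            base = cohorts.get(label)
            kwargs = dict(
                initial_distribution=dict(base.initial_distribution) if base else {},
                horizon_months=base.horizon_months if base else 60,
                nyha_label=base.nyha_label if base else NYHA_II_III,
            )
            if "initial_distribution" in spec:
                kwargs["initial_distribution"] = spec["initial_distribution"]
            for key in ("horizon_months", "nyha_label"):
                if key in spec:
                    kwargs[key] = spec[key]
            cohorts[label] = CohortSpec(label=label, **kwargs)
            if cohorts[label].nyha_label not in transitions:
                raise ConfigError(
                    f"cohorts[{label!r}].nyha_label {cohorts[label].nyha_label!r} "
                    f"names no transition column"
                )
    else:
        logger.info("config %s: no 'cohorts' section; using built-in cohorts", path)

    if "options" in raw:
        options = _parse_section("options", raw["options"], ModelOptions, _OPTION_FIELDS, defaults.options)
    else:
        options = defaults.options
        logger.info("config %s: no 'options' section; using default model options", path)

    return ParameterBundle(transitions, scenarios, costs, cohorts, options)


def bundle_to_dict(bundle: ParameterBundle) -> dict:
    """Serialize a bundle to the plain-dict form of the config dialect."""
    return {
        "transitions": {
            label: {
                "p_hosp_by_state": dict(tp.p_hosp_by_state),
                "p_death_not_hospitalized": tp.p_death_not_hospitalized,
                "p_death_hospitalized": tp.p_death_hospitalized,
            }
            for label, tp in bundle.transitions.items()
        },
        "scenarios": {
            label: {
                k: v for k, v in dataclasses.asdict(sc).items() if k != "label"
            }
            for label, sc in bundle.scenarios.items()
        },
        "costs": dataclasses.asdict(bundle.costs),
        "cohorts": {
            label: {
                "initial_distribution": {
                    s: p for s, p in co.initial_distribution.items() if p > 0
                },
                "horizon_months": co.horizon_months,
                "nyha_label": co.nyha_label,
            }
            for label, co in bundle.cohorts.items()
        },
        "options": dataclasses.asdict(bundle.options),
    }


def save_config(bundle: ParameterBundle, path: str | Path) -> None:
    """Write a bundle as a YAML config that :func:`load_config` round-trips."""
    Path(path).write_text(yaml.safe_dump(bundle_to_dict(bundle), sort_keys=True))
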