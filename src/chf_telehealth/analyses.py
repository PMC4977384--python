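"""The study's experiments: base-case comparisons, sensitivity analyses,
break-even fee solving and the two validation computations.

All routines are deterministic wrappers around the cohort engine and the
economics layer.  The incremental sign convention is telehealth minus
usual care, so a negative incremental cost is a saving.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from . import cohort_engine, economics
from .cohort_engine import adjust_hazards, life_years, run_horizon
from .parameters import (
    LIVING_STATES,
    CohortSpec,
    CostSchedule,
    EfficacyScenario,
    ModelOptions,
    ParameterError,
    TransitionParameters,
)


@dataclass(frozen=True)
class ArmOutcome:
    """Absolute outcomes of one arm, per initial patient."""

    cost: float
    life_years: float
    admissions: float


@dataclass(frozen=True)
class ComparisonResult:
    """Usual-care outcomes and telehealth increments for one cohort/horizon."""

    cohort_label: str
    horizon_months: int
    usual: ArmOutcome
    incremental: ArmOutcome  # telehealth minus usual; negative cost = saving

    @property
    def saving(self) -> float:
        """Cost saving (positive when telehealth is cheaper)."""
        return -self.incremental.cost


def _arm_outcome(
    trace, arm, tp_usual, eff, costs, options
) -> ArmOutcome:
    cost = economics.accumulate(trace, arm, tp_usual, eff, costs, options)
    rate = costs.annual_discount_rate if options.discount_life_years else 0.0
    ly = life_years(
        trace, rate, basis=options.life_year_basis, half_cycle=options.half_cycle
    )
    return ArmOutcome(cost.total, ly, float(trace.expected_admissions.sum()))


def compare_arms(
    cohort: CohortSpec,
    scenario: EfficacyScenario,
    costs: CostSchedule,
    tp: TransitionParameters,
    horizon_months: int | None = None,
    options: ModelOptions = ModelOptions(),
) -> ComparisonResult:
    """Run both arms from identical initial conditions and difference them."""
    cycles = horizon_months or cohort.horizon_months
    trace_u = run_horizon(cohort, tp, cycles)
    tp_t = adjust_hazards(
        tp, scenario, detection_gated=options.detection_gated_reductions
    )
    trace_t = run_horizon(cohort, tp_t, cycles)
    usual = _arm_outcome(trace_u, "usual", tp, None, costs, options)
    tele = _arm_outcome(trace_t, "telehealth", tp, scenario, costs, options)
    return ComparisonResult(
        cohort_label=cohort.label,
        horizon_months=cycles,
        usual=usual,
        incremental=ArmOutcome(
            tele.cost - usual.cost,
            tele.life_years - usual.life_years,
            tele.admissions - usual.admissions,
        ),
    )


_SWEEPABLE = {
    "mortality": "mortality_reduction",
    "hospitalization": "hospitalization_reduction",
    "los": "los_reduction",
}


def one_way_efficacy_sweep(
    cohort: CohortSpec,
    costs: CostSchedule,
    tp: TransitionParameters,
    horizon_months: int,
    scale_grid,
    which: str,
    scenario: EfficacyScenario,
    options: ModelOptions = ModelOptions(),
) -> list[tuple[float, float]]:
    """Incremental cost as one efficacy parameter is scaled down.

    ``which`` selects mortality, hospitalization or LOS reduction; each
    grid value multiplies that reduction fraction while the others stay
    at the reference scenario.  Returns ``(scale, incremental_cost)``
    pairs.
    """
    if which not in _SWEEPABLE:
        raise ValueError(f"which must be one of {sorted(_SWEEPABLE)}, got {which!r}")
    field = _SWEEPABLE[which]
    out = []
    for scale in scale_grid:
        if not 0.0 <= scale <= 1.0:
            raise ValueError(f"scale factors must lie in [0, 1], got {scale}")
        eff = dataclasses.replace(
            scenario,
            label=f"{scenario.label} ({which} x{scale:g})",
            **{field: getattr(scenario, field) * scale},
        )
        res = compare_arms(cohort, eff, costs, tp, horizon_months, options)
        out.append((float(scale), res.incremental.cost))
    return out


def two_way_grid(
    cohort: CohortSpec,
    scenario: EfficacyScenario,
    costs: CostSchedule,
    tp: TransitionParameters,
    horizon_months: int,
    admission_costs,
    monthly_fees,
    options: ModelOptions = ModelOptions(),
) -> np.ndarray:
    """Incremental cost matrix over (monthly fee, admission cost) pairs.

    The fee replaces the whole monthly TEST bundle; TREAT costs stay at
    their scheduled values.  Rows follow ``monthly_fees``, columns
    ``admission_costs``.
    """
    grid = np.empty((len(monthly_fees), len(admission_costs)))
    for i, fee in enumerate(monthly_fees):
        for j, adm in enumerate(admission_costs):
            c = dataclasses.replace(
                costs.with_monthly_test(fee), cost_per_admission=adm
            )
            res = compare_arms(cohort, scenario, c, tp, horizon_months, options)
            grid[i, j] = res.incremental.cost
    return grid


def break_even_fee(
    cohort: CohortSpec,
    scenario: EfficacyScenario,
    costs: CostSchedule,
    tp: TransitionParameters,
    horizon_months: int,
    options: ModelOptions = ModelOptions(),
) -> float | None:
    """Monthly TEST fee at which the incremental cost is exactly zero.

    Incremental cost is affine in the fee with slope equal to the
    discounted alive patient-months of the telehealth arm, so the root
    follows from two evaluations.  Returns ``None`` ("never") when the
    program is cost-incurring even at a zero fee.
    """
    def delta(fee: float) -> float:
        c = costs.with_monthly_test(fee)
        return compare_arms(cohort, scenario, c, tp, horizon_months, options).incremental.cost

    d0 = delta(0.0)
    if d0 > 0.0:
        return None
    slope = (delta(100.0) - d0) / 100.0  # discounted alive-months per $ of fee
    return -d0 / slope + 0.0  # +0.0 normalizes -0.0 at exact break-even


def lifetime_validation(
    tp: TransitionParameters,
    costs: CostSchedule,
    horizon_months: int = 240,
    options: ModelOptions = ModelOptions(),
) -> float:
    """Usual-care discounted lifetime cost of a newly diagnosed cohort.

    Runs the no-prior-admission cohort over a 20-year horizon (by which
    point nearly the whole cohort has died) and totals discounted usual
    care costs.
    """
    cohort = CohortSpec({"H0": 1.0}, horizon_months, tp.label, label="C1")
    trace = run_horizon(cohort, tp, horizon_months)
    return economics.accumulate(trace, "usual", tp, None, costs, options).total


def national_burden(
    tp: TransitionParameters,
    costs: CostSchedule,
    weights,
    population: float,
    options: ModelOptions = ModelOptions(),
    *,
    include_non_chf: bool = False,
) -> float:
    """Yearly direct CHF cost for a population, usual care, USD per year.

    ``weights`` distributes the population over the living states by
    prior-admission count.  Only CHF-attributable channels (admissions
    and CHF outpatient care) are counted unless ``include_non_chf`` is
    set.
    """
    if population < 0:
        raise ParameterError(f"population must be >= 0, got {population}")
    weights = list(weights)
    if len(weights) != len(LIVING_STATES):
        raise ParameterError(
            f"weights must cover the {len(LIVING_STATES)} living states"
        )
    if abs(sum(weights) - 1.0) > 1e-9:
        raise ParameterError(f"weights must sum to 1, got {sum(weights)!r}")
    cohort = CohortSpec(
        dict(zip(LIVING_STATES, weights)), 12, tp.label, label="national"
    )
    trace = run_horizon(cohort, tp, 12)
    cost = economics.accumulate(trace, "usual", tp, None, costs, options)
    channels = ["admission", "outpatient"] + (["non_chf"] if include_non_chf else [])
    per_patient = float(sum(cost.components[c].sum() for c in channels))
    return per_patient * population
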