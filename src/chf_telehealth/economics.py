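"""Discounted cost accrual for each study arm from a cohort trace.

Both arms accrue the per-admission cost and the fixed monthly outpatient
and non-CHF costs (annual figures divided by 12, charged to patients
alive at cycle start).  The telehealth arm additionally pays the monthly
TEST (monitoring) bundle for every alive patient and a TREAT
(early-intervention) cost for every positive detection — true positives
at rate SEN among exacerbating patients and false positives at rate
1 − SPE among the rest.  Detected admissions are billed at a length-of-
stay-reduced rate.  All components are discounted to present value at the
annual rate with an end-of-cycle monthly convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .cohort_engine import CohortTrace, StateVector, adjust_hazards
from .parameters import (
    CostSchedule,
    EfficacyScenario,
    ModelOptions,
    TransitionParameters,
)

ARMS = ("usual", "telehealth")
COMPONENTS = ("admission", "outpatient", "non_chf", "test", "treat")


@dataclass(frozen=True)
class CostTrace:
    """Discounted cost accrual per initial patient.

    ``components`` maps each cost channel to a per-cycle array;
    ``per_cycle_cost`` is their sum and ``total`` the grand total.
    """

    per_cycle_cost: np.ndarray
    components: Mapping[str, np.ndarray]
    total: float


def discount_factor(cycle: int, annual_rate: float) -> float:
    """Present-value multiplier for month ``cycle`` (1-based, end-of-cycle)."""
    if cycle < 1:
        raise ValueError(f"cycle index is 1-based, got {cycle}")
    return (1.0 + annual_rate) ** (-cycle / 12.0)


def expected_treat_cost(
    p_exacerbation: float, eff: EfficacyScenario, costs: CostSchedule
) -> float:
    """Expected TREAT cost per alive patient-cycle.

    A patient exacerbating with probability ``p_exacerbation`` triggers a
    positive test with probability SEN; a non-exacerbating patient with
    probability 1 − SPE.  Every positive test incurs the physician +
    nurse-visit episode cost.
    """
    p_positive = (
        eff.sensitivity * p_exacerbation
        + (1.0 - eff.specificity) * (1.0 - p_exacerbation)
    )
    return p_positive * costs.treat_per_episode


def _admission_multiplier(eff: EfficacyScenario, options: ModelOptions) -> float:
    """Per-admission cost multiplier in the telehealth arm (LOS saving)."""
    if options.los_gating == "sen":
        return eff.sensitivity * (1.0 - eff.los_reduction) + (1.0 - eff.sensitivity)
    return 1.0 - eff.los_reduction


def cycle_cost(
    arm: str,
    occupancy: StateVector,
    expected_admissions: float,
    tp_usual: TransitionParameters,
    eff: EfficacyScenario | None,
    costs: CostSchedule,
    cycle: int,
    options: ModelOptions = ModelOptions(),
) -> dict[str, float]:
    """Discounted cost breakdown for one cycle, per initial patient.

    ``occupancy`` is the state distribution at cycle start and
    ``expected_admissions`` the expected admission events of this cycle
    in the arm being costed.  ``eff`` is ignored for the usual arm.
    """
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")
    alive = occupancy.alive
    disc = discount_factor(cycle, costs.annual_discount_rate)

    out = {
        "outpatient": alive * costs.annual_chf_outpatient / 12.0,
        "non_chf": alive * costs.annual_non_chf / 12.0,
        "test": 0.0,
        "treat": 0.0,
    }
    if arm == "usual":
        out["admission"] = expected_admissions * costs.cost_per_admission
    else:
        if eff is None:
            raise ValueError("telehealth arm requires an EfficacyScenario")
        out["test"] = alive * costs.monthly_test
        if options.treat_trigger == "usual":
            trigger_tp = tp_usual
        else:
            trigger_tp = adjust_hazards(
                tp_usual, eff, detection_gated=options.detection_gated_reductions
            )
        live = occupancy.mass[: len(trigger_tp.p_hosp_by_state)]
        p_ex = float((live * trigger_tp.hosp_array()).sum()) / alive if alive > 0 else 0.0
        out["treat"] = alive * expected_treat_cost(p_ex, eff, costs)
        out["admission"] = (
            expected_admissions
            * costs.cost_per_admission
            * _admission_multiplier(eff, options)
        )
    return {k: v * disc for k, v in out.items()}


def accumulate(
    trace: CohortTrace,
    arm: str,
    tp_usual: TransitionParameters,
    eff: EfficacyScenario | None,
    costs: CostSchedule,
    options: ModelOptions = ModelOptions(),
) -> CostTrace:
    """Apply :func:`cycle_cost` over a full trace."""
    n = trace.cycles
    components = {k: np.zeros(n) for k in COMPONENTS}
    for t in range(n):
        occ = trace.state_vector(t)
        if options.half_cycle:
            # average the start- and end-of-cycle distributions
            mass = 0.5 * (trace.occupancy[t] + trace.occupancy[t + 1])
            occ = StateVector(mass)
        breakdown = cycle_cost(
            arm, occ, trace.expected_admissions[t], tp_usual, eff, costs, t + 1, options
        )
        for k, v in breakdown.items():
            components[k][t] = v
    per_cycle = sum(components.values())
    return CostTrace(per_cycle, components, float(per_cycle.sum()))
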