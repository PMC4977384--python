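"""Deterministic monthly propagation of a cohort through the 6-state model.

States are counts of prior CHF hospital admissions (H0..H4plus) plus an
absorbing death state.  Within each monthly cycle a living patient first
either has a hospitalization event (probability ``p_hosp_by_state[H]``) or
not; death is then resolved conditionally on that outcome
(``p_death_hospitalized`` given an admission, ``p_death_not_hospitalized``
otherwise).  Survivors of an admission advance one state (capped at
H4plus); other survivors stay put.  There is no recovery transition.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .parameters import (
    LIVING_STATES,
    STATES,
    CohortSpec,
    EfficacyScenario,
    TransitionParameters,
)

_DEATH = len(STATES) - 1
_N_LIVING = len(LIVING_STATES)


@dataclass(frozen=True)
class StateVector:
    """Probability mass over the six model states."""

    mass: np.ndarray

    def __post_init__(self) -> None:
        mass = np.asarray(self.mass, dtype=float)
        if mass.shape != (len(STATES),):
            raise ValueError(f"state vector must have {len(STATES)} components")
        if (mass < -1e-12).any() or (mass > 1 + 1e-12).any():
            raise ValueError(f"state masses must lie in [0, 1]: {mass}")
        if abs(mass.sum() - 1.0) > 1e-10:
            raise ValueError(f"state masses must sum to 1, got {mass.sum()!r}")
        object.__setattr__(self, "mass", mass)

    @classmethod
    def from_cohort(cls, cohort: CohortSpec) -> "StateVector":
        return cls(cohort.mass_array())

    @property
    def alive(self) -> float:
        return float(self.mass[:_N_LIVING].sum())

    @property
    def dead(self) -> float:
        return float(self.mass[_DEATH])

    def __getitem__(self, state: str) -> float:
        return float(self.mass[STATES.index(state)])


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle record of a cohort run.

    ``occupancy`` has ``cycles + 1`` rows (row 0 is the initial
    distribution); the per-cycle arrays have one entry per cycle, all
    expressed per initial patient.
    """

    occupancy: np.ndarray
    expected_admissions: np.ndarray
    expected_deaths: np.ndarray
    alive_at_start: np.ndarray

    @property
    def cycles(self) -> int:
        return len(self.expected_admissions)

    @property
    def alive_at_end(self) -> np.ndarray:
        """Fraction alive at the end of each cycle."""
        return 1.0 - self.occupancy[1:, _DEATH]

    def state_vector(self, cycle: int) -> StateVector:
        return StateVector(self.occupancy[cycle])


def adjust_hazards(
    base: TransitionParameters,
    eff: EfficacyScenario,
    *,
    detection_gated: bool = False,
) -> TransitionParameters:
    """Apply proportional efficacy reductions to the usual-care hazards.

    Each hospitalization probability is multiplied by
    ``1 - hospitalization_reduction`` and both death probabilities by
    ``1 - mortality_reduction``.  With ``detection_gated`` the reduction
    fractions are first scaled by the test sensitivity, reflecting that
    undetected exacerbations receive no early intervention.  Sensitivity,
    specificity and the LOS reduction never alter hazards otherwise.
    """
    gate = eff.sensitivity if detection_gated else 1.0
    hosp_factor = 1.0 - eff.hospitalization_reduction * gate
    death_factor = 1.0 - eff.mortality_reduction * gate
    return TransitionParameters(
        p_hosp_by_state={s: p * hosp_factor for s, p in base.p_hosp_by_state.items()},
        p_death_not_hospitalized=base.p_death_not_hospitalized * death_factor,
        p_death_hospitalized=base.p_death_hospitalized * death_factor,
        label=f"{base.label} ({eff.label} telehealth)",
    )


def step_cycle(
    state: StateVector, tp: TransitionParameters
) -> tuple[StateVector, float, float]:
    """Advance the cohort one month.

    Returns the new state vector together with the expected number of
    hospitalization events and of deaths during the cycle, per initial
    patient.
    """
    mass = state.mass
    live = mass[:_N_LIVING]
    p_h = tp.hosp_array()
    p_dh = tp.p_death_hospitalized
    p_dnh = tp.p_death_not_hospitalized

    admissions = float((live * p_h).sum())
    deaths = float((live * (p_h * p_dh + (1.0 - p_h) * p_dnh)).sum())

    survive_hosp = live * p_h * (1.0 - p_dh)
    stay = live * (1.0 - p_h) * (1.0 - p_dnh)

    new = np.zeros_like(mass)
    new[:_N_LIVING] = stay
    new[1:_N_LIVING] += survive_hosp[:-1]
    new[_N_LIVING - 1] += survive_hosp[-1]  # H4plus is a ceiling
    new[_DEATH] = mass[_DEATH] + deaths
    return StateVector(new), admissions, deaths


def run_horizon(
    cohort: CohortSpec, tp: TransitionParameters, cycles: int | None = None
) -> CohortTrace:
    """Iterate :func:`step_cycle` from the cohort's initial distribution."""
    if cycles is None:
        cycles = cohort.horizon_months
    if cycles < 1:
        raise ValueError(f"cycles must be >= 1, got {cycles}")
    state = StateVector.from_cohort(cohort)
    occupancy = np.empty((cycles + 1, len(STATES)))
    occupancy[0] = state.mass
    admissions = np.empty(cycles)
    deaths = np.empty(cycles)
    alive_at_start = np.empty(cycles)
    for t in range(cycles):
        alive_at_start[t] = state.alive
        state, admissions[t], deaths[t] = step_cycle(state, tp)
        occupancy[t + 1] = state.mass
    return CohortTrace(occupancy, admissions, deaths, alive_at_start)


def life_years(
    trace: CohortTrace,
    annual_discount_rate: float = 0.0,
    *,
    basis: str = "end",
    half_cycle: bool = False,
) -> float:
    """Expected alive person-time per initial patient, in years.

    Each monthly cycle contributes the surviving fraction divided by 12,
    optionally discounted at ``annual_discount_rate`` with the same
    end-of-cycle convention used for costs.  ``basis`` selects whether the
    fraction alive is taken at cycle end (default) or cycle start;
    ``half_cycle`` averages the two.
    """
    if basis not in ("start", "end"):
        raise ValueError(f"basis must be 'start' or 'end', got {basis!r}")
    alive = trace.alive_at_start if basis == "start" else trace.alive_at_end
    if half_cycle:
        alive = 0.5 * (trace.alive_at_start + trace.alive_at_end)
    t = np.arange(1, trace.cycles + 1)
    disc = (1.0 + annual_discount_rate) ** (-t / 12.0)
    return float((alive / 12.0 * disc).sum())
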