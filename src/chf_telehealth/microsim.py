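"""Individual-level Monte Carlo simulator of the same monthly event logic.

The cohort engine propagates expectations; this module draws actual
patient trajectories under the identical event ordering and cost rules,
serving as a brute-force oracle for the deterministic results and as a
generator of synthetic patient-level data (the model's hazards are the
data-generating process — no real patient records are involved).

Randomness comes from a counter-based Philox stream keyed by the seed.
Each patient owns a fixed contiguous block of the stream (one draw for
the initial state plus four per cycle), so enlarging ``n_patients`` at a
given horizon appends new patients without reshuffling existing ones.
Running both arms with the same seed reuses the same uniforms (common
random numbers), which makes the averted-admission subpopulation
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort_engine import adjust_hazards
from .economics import _admission_multiplier, discount_factor
from .parameters import (
    LIVING_STATES,
    STATES,
    CohortSpec,
    CostSchedule,
    EfficacyScenario,
    ModelOptions,
    TransitionParameters,
)

_DEATH = len(STATES) - 1
_DRAWS_PER_CYCLE = 4  # hospitalization, death-in-hosp, death-out, test


@dataclass(frozen=True)
class MicrosimResult:
    """Per-patient outcomes plus Monte-Carlo summary statistics."""

    n_patients: int
    cycles: int
    seed: int
    arm: str
    cost: np.ndarray          # per-patient discounted total cost
    life_years: np.ndarray    # per-patient (optionally discounted) life years
    admissions: np.ndarray    # per-patient admission count
    died: np.ndarray          # per-patient death indicator
    occupancy: np.ndarray     # empirical state fractions, (cycles+1, 6)
    test_counts: dict = field(default_factory=dict)  # TP/FP/TN/FN totals
    trajectories: pd.DataFrame | None = None

    def _mean_se(self, x: np.ndarray) -> tuple[float, float]:
        return float(x.mean()), float(x.std(ddof=1) / np.sqrt(len(x)))

    @property
    def summary(self) -> dict[str, float]:
        out = {}
        for name, arr in (
            ("cost", self.cost),
            ("life_years", self.life_years),
            ("admissions", self.admissions),
        ):
            mean, se = self._mean_se(arr)
            out[f"mean_{name}"] = mean
            out[f"se_{name}"] = se
        out["mean_deaths"] = float(self.died.mean())
        return out


def _initial_states(cohort: CohortSpec, u: np.ndarray) -> np.ndarray:
    cdf = np.cumsum(cohort.mass_array())
    return np.searchsorted(cdf, u, side="right").astype(np.int8)


def simulate(
    cohort: CohortSpec,
    tp: TransitionParameters,
    eff: EfficacyScenario | None,
    costs: CostSchedule,
    n_patients: int,
    seed: int,
    cycles: int | None = None,
    options: ModelOptions = ModelOptions(),
    keep_trajectories: bool = False,
) -> MicrosimResult:
    """Simulate ``n_patients`` trajectories through one arm.

    ``eff=None`` runs usual care; otherwise the telehealth arm with the
    given efficacy scenario.  Reproducible for a given seed.
    """
    if n_patients < 1:
        raise ValueError(f"n_patients must be >= 1, got {n_patients}")
    T = cycles or cohort.horizon_months
    arm = "usual" if eff is None else "telehealth"

    if eff is not None:
        tp_arm = adjust_hazards(
            tp, eff, detection_gated=options.detection_gated_reductions
        )
        trigger_tp = tp if options.treat_trigger == "usual" else tp_arm
        adm_mult_all = 1.0 - eff.los_reduction
    else:
        tp_arm = tp
        trigger_tp = tp

    ph = tp_arm.hosp_array()
    ph_trigger = trigger_tp.hosp_array()
    p_dh = tp_arm.p_death_hospitalized
    p_dnh = tp_arm.p_death_not_hospitalized
    fixed_monthly = (costs.annual_chf_outpatient + costs.annual_non_chf) / 12.0
    rate = costs.annual_discount_rate
    ly_rate = rate if options.discount_life_years else 0.0

    gen = np.random.Generator(np.random.Philox(key=seed))
    u = gen.random(n_patients * (1 + _DRAWS_PER_CYCLE * T)).reshape(
        n_patients, 1 + _DRAWS_PER_CYCLE * T
    )
    state = _initial_states(cohort, u[:, 0])
    alive = state < _DEATH

    cost = np.zeros(n_patients)
    ly = np.zeros(n_patients)
    admissions = np.zeros(n_patients, dtype=np.int32)
    occupancy = np.zeros((T + 1, len(STATES)))
    occupancy[0] = np.bincount(state, minlength=len(STATES)) / n_patients
    counts = {"TP": 0, "FP": 0, "TN": 0, "FN": 0}
    if keep_trajectories:
        traj_state = np.empty((n_patients, T + 1), dtype=np.int8)
        traj_state[:, 0] = state
        traj_hosp = np.zeros((n_patients, T), dtype=bool)
        traj_death = np.zeros((n_patients, T), dtype=bool)
        traj_positive = np.zeros((n_patients, T), dtype=bool)

    for t in range(1, T + 1):
        base = 1 + _DRAWS_PER_CYCLE * (t - 1)
        u_hosp, u_dh, u_dnh, u_test = (u[:, base + k] for k in range(4))
        live_state = np.where(alive, state, 0)  # safe index; masked below

        hosp = alive & (u_hosp < ph[live_state])
        die = (hosp & (u_dh < p_dh)) | (alive & ~hosp & (u_dnh < p_dnh))
        admissions += hosp

        disc = discount_factor(t, rate)
        alive_end = alive & ~die
        if options.half_cycle:
            accrual = 0.5 * (alive.astype(float) + alive_end.astype(float))
        else:
            accrual = alive.astype(float)
        cost += accrual * fixed_monthly * disc

        if eff is not None:
            cost += accrual * costs.monthly_test * disc
            exac = alive & (u_hosp < ph_trigger[live_state])
            positive = alive & np.where(exac, u_test < eff.sensitivity,
                                        u_test < 1.0 - eff.specificity)
            counts["TP"] += int((exac & positive).sum())
            counts["FN"] += int((exac & ~positive & alive).sum())
            counts["FP"] += int((~exac & positive & alive).sum())
            counts["TN"] += int((~exac & ~positive & alive).sum())
            cost += positive * costs.treat_per_episode * disc
            if options.los_gating == "sen":
                detected = hosp & (u_test < eff.sensitivity)
                adm_cost = np.where(detected, adm_mult_all, 1.0) * hosp
            else:
                adm_cost = hosp * adm_mult_all
            cost += adm_cost * costs.cost_per_admission * disc
            if keep_trajectories:
                traj_positive[:, t - 1] = positive
        else:
            cost += hosp * costs.cost_per_admission * disc

        ly_alive = alive if options.life_year_basis == "start" else alive_end
        if options.half_cycle:
            ly_contrib = 0.5 * (alive.astype(float) + alive_end.astype(float))
        else:
            ly_contrib = ly_alive.astype(float)
        ly += ly_contrib / 12.0 * discount_factor(t, ly_rate)

        advanced = np.minimum(state + 1, len(LIVING_STATES) - 1).astype(np.int8)
        state = np.where(hosp & ~die, advanced, state)
        state = np.where(die, _DEATH, state).astype(np.int8)
        alive = alive_end
        occupancy[t] = np.bincount(state, minlength=len(STATES)) / n_patients
        if keep_trajectories:
            traj_state[:, t] = state
            traj_hosp[:, t - 1] = hosp
            traj_death[:, t - 1] = die

    trajectories = None
    if keep_trajectories:
        pid, cyc = np.meshgrid(
            np.arange(n_patients), np.arange(1, T + 1), indexing="ij"
        )
        trajectories = pd.DataFrame(
            {
                "patient": pid.ravel(),
                "cycle": cyc.ravel(),
                "state": np.array(
                    [STATES[s] for s in traj_state[:, 1:].ravel()]
                ),
                "hospitalized": traj_hosp.ravel(),
                "died": traj_death.ravel(),
                "test_positive": traj_positive.ravel(),
            }
        )

    return MicrosimResult(
        n_patients=n_patients,
        cycles=T,
        seed=seed,
        arm=arm,
        cost=cost,
        life_years=ly,
        admissions=admissions,
        died=state == _DEATH,
        occupancy=occupancy,
        test_counts=counts,
        trajectories=trajectories,
    )
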