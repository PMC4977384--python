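"""Experiment orchestration: sweeps, grids, break-even, validation runs."""

import dataclasses

import numpy as np
import pytest
from scipy.optimize import brentq

from chf_telehealth import (
    EfficacyScenario,
    break_even_fee,
    compare_arms,
    lifetime_validation,
    national_burden,
    one_way_efficacy_sweep,
    two_way_grid,
)
from chf_telehealth.parameters import ParameterError

SCALES = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]
BURDEN_WEIGHTS = [0.707, 0.103, 0.044, 0.033, 0.113]


def test_null_intervention_all_increments_zero(defaults, tp, options):
    free = dataclasses.replace(
        defaults.costs, monthly_install=0.0, monthly_monitoring=0.0,
        monthly_case_manager=0.0, treat_physician=0.0, treat_nurse_visit=0.0,
    )
    res = compare_arms(
        defaults.cohorts["C1"], EfficacyScenario.null(), free, tp, 12, options
    )
    assert res.incremental.cost == pytest.approx(0, abs=1e-9)
    assert res.incremental.life_years == pytest.approx(0, abs=1e-12)
    assert res.incremental.admissions == pytest.approx(0, abs=1e-12)


def test_sweep_identity_at_full_scale(defaults, tp, base, costs, options):
    cohort = defaults.cohorts["C2"]
    reference = compare_arms(cohort, base, costs, tp, 36, options).incremental.cost
    for which in ("mortality", "hospitalization", "los"):
        points = one_way_efficacy_sweep(
            cohort, costs, tp, 36, [1.0], which, base, options
        )
        assert points[0][1] == pytest.approx(reference)


@pytest.mark.parametrize(
    "which,direction",
    [("los", "nonincreasing"), ("hospitalization", "nonincreasing"),
     ("mortality", "nondecreasing")],
)
def test_sweep_monotonicity(defaults, tp, base, costs, options, which, direction):
    """Scaling up LOS/hospitalization effects saves money; scaling up the
    mortality effect costs money (survivors keep accruing costs)."""
    points = one_way_efficacy_sweep(
        defaults.cohorts["C2"], costs, tp, 36, SCALES, which, base, options
    )
    deltas = np.diff([cost for _, cost in points])
    if direction == "nonincreasing":
        assert (deltas <= 1e-9).all()
    else:
        assert (deltas >= -1e-9).all()


def test_sweep_rejects_bad_input(defaults, tp, base, costs, options):
    with pytest.raises(ValueError, match="which"):
        one_way_efficacy_sweep(
            defaults.cohorts["C2"], costs, tp, 12, [1.0], "specificity", base, options
        )
    with pytest.raises(ValueError, match="scale"):
        one_way_efficacy_sweep(
            defaults.cohorts["C2"], costs, tp, 12, [1.5], "los", base, options
        )


def test_two_way_grid_affine_structure(defaults, tp, base, costs, options):
    """Incremental cost is affine in the fee (rows) and admission cost (cols)."""
    fees = [50.0, 150.0, 250.0]
    adms = [6000.0, 8000.0, 10000.0]
    grid = two_way_grid(
        defaults.cohorts["C2"], base, costs, tp, 36, adms, fees, options
    )
    assert grid.shape == (3, 3)
    np.testing.assert_allclose(np.diff(grid, n=2, axis=0), 0, atol=1e-6)
    np.testing.assert_allclose(np.diff(grid, n=2, axis=1), 0, atol=1e-6)
    # more expensive admissions -> more saving; higher fee -> less saving
    assert (np.diff(grid, axis=1) < 0).all()
    assert (np.diff(grid, axis=0) > 0).all()


def test_break_even_matches_bisection(defaults, tp, base, costs, options):
    """Closed-form root agrees with bracketing on the cost difference."""
    for label in ("C2", "C3"):
        cohort = defaults.cohorts[label]
        fee = break_even_fee(cohort, base, costs, tp, 12, options)

        def delta(f):
            return compare_arms(
                cohort, base, costs.with_monthly_test(f), tp, 12, options
            ).incremental.cost

        root = brentq(delta, 0.0, 2000.0, xtol=1e-6)
        assert fee == pytest.approx(root, abs=0.01)
        assert delta(fee) == pytest.approx(0.0, abs=1e-6)


def test_break_even_never_when_cost_incurring(defaults, tp, costs, options):
    """A program with no clinical benefit but false-positive treatment
    costs can never pay for itself; a free do-nothing program breaks even
    at exactly zero."""
    wasteful = EfficacyScenario(0.0, 0.5, 0.0, 0.0, 0.0)
    assert (
        break_even_fee(defaults.cohorts["C1"], wasteful, costs, tp, 12, options)
        is None
    )
    assert break_even_fee(
        defaults.cohorts["C1"], EfficacyScenario.null(), costs, tp, 12, options
    ) == pytest.approx(0.0)


def test_break_even_ordering_by_risk(defaults, tp, costs, options):
    """Higher-risk cohorts tolerate higher fees, in every scenario/horizon."""
    for scenario in defaults.scenarios.values():
        for horizon in (12, 36, 60):
            fees = [
                break_even_fee(defaults.cohorts[c], scenario, costs, tp, horizon, options)
                for c in ("C1", "C2", "C3")
            ]
            numeric = [-np.inf if f is None else f for f in fees]
            assert numeric[0] <= numeric[1] <= numeric[2]


def test_lifetime_cost_grows_without_mortality(defaults, tp, costs, options):
    immortal = dataclasses.replace(
        tp, p_death_not_hospitalized=0.0, p_death_hospitalized=0.0
    )
    short = lifetime_validation(immortal, costs, 120, options)
    long = lifetime_validation(immortal, costs, 240, options)
    assert long > short * 1.5  # keeps accruing, no saturation
    # with real hazards most of the cohort has died by 20 years
    trace_cost = lifetime_validation(tp, costs, 240, options)
    assert trace_cost < long


def test_national_burden_scaling(defaults, tp, costs, options):
    assert national_burden(tp, costs, BURDEN_WEIGHTS, 0, options) == 0.0
    one = national_burden(tp, costs, BURDEN_WEIGHTS, 1_000_000, options)
    five = national_burden(tp, costs, BURDEN_WEIGHTS, 5_000_000, options)
    assert five == pytest.approx(5 * one)
    with_non_chf = national_burden(
        tp, costs, BURDEN_WEIGHTS, 1_000_000, options, include_non_chf=True
    )
    assert with_non_chf > one


def test_national_burden_weight_validation(tp, costs, options):
    with pytest.raises(ParameterError, match="sum to 1"):
        national_burden(tp, costs, [0.5, 0.1, 0.1, 0.1, 0.1], 100, options)
    with pytest.raises(ParameterError, match="living states"):
        national_burden(tp, costs, [1.0], 100, options)
    with pytest.raises(ParameterError, match="population"):
        national_burden(tp, costs, BURDEN_WEIGHTS, -5, options)


def test_clinical_increments_never_harmful(defaults, tp, costs, options):
    """Under every published scenario, telehealth adds life years and
    removes admissions for every cohort."""
    for scenario in defaults.scenarios.values():
        for cohort in defaults.cohorts.values():
            res = compare_arms(cohort, scenario, costs, tp, 36, options)
            assert res.incremental.life_years >= 0
            assert res.incremental.admissions <= 0
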