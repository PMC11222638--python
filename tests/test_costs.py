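"""Cost/utility accumulation: dosing arithmetic, schedules, outcomes."""

import dataclasses
import math

import numpy as np
import pytest

from dcpcea.cohort import Horizon, run_trace
from dcpcea.costs import (
    AEProfile,
    CostInputs,
    StrategyEvaluator,
    StrategyOutcome,
    UtilityInputs,
    ae_burden,
    drug_cost_per_administration,
    end_of_life_cost,
    icer,
    imaging_cost_schedule,
    imaging_scan_cycles,
    maintenance_cycles,
    progression_state_cost_per_cycle,
)
from dcpcea.survival import SurvivalModel

PRICES = CostInputs()


def test_bsa_and_flat_dose_arithmetic():
    # paclitaxel 175 mg/m2 at BSA 1.84 -> 322 mg at $0.108/mg
    assert drug_cost_per_administration("paclitaxel", PRICES) == pytest.approx(
        322 * 0.108
    )
    # dostarlimab 500 mg -> 50 ten-mg units
    assert drug_cost_per_administration("dostarlimab", PRICES, dose_mg=500.0) == pytest.approx(
        50 * 233.258
    )
    # Calvert: AUC 5 * (GFR 70 + 25) = 475 mg -> 9.5 fifty-mg units
    assert drug_cost_per_administration("carboplatin", PRICES) == pytest.approx(
        9.5 * 3.599
    )
    # doxorubicin 60 mg/m2 -> 110.4 mg -> 11.04 ten-mg units
    assert drug_cost_per_administration("doxorubicin", PRICES) == pytest.approx(
        11.04 * 3.279
    )
    with pytest.raises(ValueError):
        drug_cost_per_administration("bevacizumab", PRICES)


def test_whole_vial_rounding_flag():
    whole = dataclasses.replace(PRICES, whole_vial=True)
    # carboplatin 9.5 units rounds up to 10 vials
    assert drug_cost_per_administration("carboplatin", whole) == pytest.approx(10 * 3.599)
    # flat 50-unit dose unchanged
    assert drug_cost_per_administration("dostarlimab", whole, dose_mg=500.0) == pytest.approx(
        50 * 233.258
    )


def test_imaging_schedule():
    assert imaging_cost_schedule(2) == pytest.approx(651.81)  # week 6 scan
    assert imaging_cost_schedule(3) == 0.0  # week 9, off-schedule
    cycles = imaging_scan_cycles()
    # 6-weekly to week 25, 9-weekly to week 52: seven scans in year one
    assert sum(1 for c in cycles if c * 3 <= 52) == 7
    # 12-weekly afterwards: consecutive later scans 4 cycles apart
    late = [c for c in cycles if c * 3 > 52]
    assert all(b - a == 4 for a, b in zip(late, late[1:]))
    with pytest.raises(ValueError):
        imaging_cost_schedule(0)


def test_maintenance_dosing_cycles():
    cycles = maintenance_cycles()
    assert cycles[0] == 7  # first dose after six induction cycles
    assert np.all(np.diff(cycles) == 2)  # every 6 weeks = every 2nd cycle
    assert len(cycles) == 23  # through cycle 51 (36-month cap)
    hz = Horizon()
    assert cycles[-1] * hz.cycle_months <= 36.0 + hz.cycle_months


def test_ae_burden_against_hand_computed_sums(dmmr_scenario):
    cost, dis = ae_burden(dmmr_scenario.ae_profiles["DCP"])
    assert cost == pytest.approx(11041.52973, abs=0.01)
    assert dis == pytest.approx(0.048747, abs=1e-6)
    cost_cp, dis_cp = ae_burden(dmmr_scenario.ae_profiles["CP"])
    assert cost_cp == pytest.approx(11581.45595, abs=0.01)
    assert dis_cp == pytest.approx(0.052429, abs=1e-6)
    empty = AEProfile((), np.array([]), np.array([]), np.array([]))
    assert ae_burden(empty) == (0.0, 0.0)


def test_progression_state_cost_components():
    no_subseq = dataclasses.replace(
        PRICES, subsequent_fraction_dcp=0.0, subsequent_fraction_cp=0.0
    )
    # nobody on active therapy: best supportive care plus the physician visit
    assert progression_state_cost_per_cycle("CP", 0, no_subseq) == pytest.approx(
        1300.61 + 164.04
    )
    # all on pembrolizumab: 200 mg at $55.73/mg plus admin+labs on treatment
    all_pem = dataclasses.replace(PRICES, subsequent_fraction_cp=1.0, doxorubicin_split=0.0)
    assert progression_state_cost_per_cycle("CP", 10, all_pem) == pytest.approx(
        200 * 55.730 + 149.69 + 359.16 + 164.04
    )
    # doxorubicin course ends after six cycles
    all_dox = dataclasses.replace(PRICES, subsequent_fraction_cp=1.0, doxorubicin_split=1.0)
    early = progression_state_cost_per_cycle("CP", 0, all_dox)
    late = progression_state_cost_per_cycle("CP", 6, all_dox)
    assert early == pytest.approx(11.04 * 3.279 + 149.69 + 359.16 + 164.04)
    assert late == pytest.approx(1300.61 + 164.04)
    # optional pembrolizumab cap reverts to supportive care
    capped = dataclasses.replace(
        PRICES, subsequent_fraction_cp=1.0, doxorubicin_split=0.0,
        pembrolizumab_cap_months=24.0,
    )
    assert progression_state_cost_per_cycle("CP", 40, capped) == pytest.approx(
        1300.61 + 164.04
    )
    with pytest.raises(ValueError):
        progression_state_cost_per_cycle("XX", 0, PRICES)


def test_end_of_life_cost_closed_forms():
    rate = 0.1
    os_ = SurvivalModel("exponential", {"rate": rate})
    trace = run_trace(os_, os_)
    # no discounting: one-time cost times cumulative mortality
    total = end_of_life_cost(trace, PRICES, 0.0)
    t_end = trace.horizon.n_cycles * trace.horizon.cycle_months
    assert total == pytest.approx(37590.23 * (1 - math.exp(-rate * t_end)), rel=1e-6)
    # discounted version is strictly smaller
    assert end_of_life_cost(trace, PRICES, 0.03) < total
    # immortal cohort: no end-of-life cost
    alive = SurvivalModel("exponential", {"rate": 1e-12})
    assert end_of_life_cost(run_trace(alive, alive), PRICES, 0.03) == pytest.approx(0.0, abs=1e-3)


def test_icer_labels_and_published_rounding():
    res = icer(StrategyOutcome(685620.0, 8.97), StrategyOutcome(354873.0, 3.49))
    assert res.delta_cost == pytest.approx(330747.0)
    assert res.delta_qaly == pytest.approx(5.48)
    assert res.icer == pytest.approx(60355.29, abs=0.01)
    same = icer(StrategyOutcome(10.0, 1.0), StrategyOutcome(10.0, 1.0))
    assert same.icer is None and same.label is None
    undef = icer(StrategyOutcome(20.0, 1.0), StrategyOutcome(10.0, 1.0))
    assert undef.label == "undefined"
    dom = icer(StrategyOutcome(10.0, 2.0), StrategyOutcome(20.0, 1.0))
    assert dom.label == "dominant"
    dominated = icer(StrategyOutcome(20.0, 1.0), StrategyOutcome(10.0, 2.0))
    assert dominated.label == "dominated"


def test_zero_utilities_zero_qalys(dmmr_scenario, dmmr_eval):
    zero_u = UtilityInputs(u_pfs=0.0, u_pd=0.0, u_death=0.0)
    no_ae = AEProfile((), np.array([]), np.array([]), np.array([]))
    out = dmmr_eval.evaluate("DCP", utilities=zero_u, ae=no_ae)
    assert out.qaly == pytest.approx(0.0, abs=1e-12)
    base = dmmr_eval.evaluate("DCP", ae=no_ae)
    assert out.cost == pytest.approx(base.cost)  # prices unaffected by utilities


@pytest.mark.parametrize(
    "field",
    ["dostarlimab_per_10mg", "bsc_per_cycle", "imaging_per_scan", "end_of_life",
     "physician_visit_per_cycle", "paclitaxel_per_mg"],
)
def test_cost_increases_in_unit_prices_and_qalys_do_not(dmmr_eval, field):
    base = dmmr_eval.evaluate("DCP")
    bumped = dataclasses.replace(
        dmmr_eval.scenario.costs, **{field: getattr(dmmr_eval.scenario.costs, field) * 1.5}
    )
    out = dmmr_eval.evaluate("DCP", prices=bumped)
    assert out.cost > base.cost
    assert out.qaly == pytest.approx(base.qaly)


def test_removing_pd_costs_leaves_only_eol_after_progression(dmmr_eval):
    stripped = dataclasses.replace(
        dmmr_eval.scenario.costs,
        subsequent_fraction_dcp=0.0,
        subsequent_fraction_cp=0.0,
        bsc_per_cycle=0.0,
        physician_visit_per_cycle=0.0,
    )
    out = dmmr_eval.evaluate("CP", prices=stripped)
    # post-progression drugs can no longer matter
    pricier_pem = dataclasses.replace(stripped, pembrolizumab_per_mg=10 * 55.73)
    assert dmmr_eval.evaluate("CP", prices=pricier_pem).cost == pytest.approx(out.cost)
    # but end-of-life cost still accrues
    no_eol = dataclasses.replace(stripped, end_of_life=0.0)
    assert dmmr_eval.evaluate("CP", prices=no_eol).cost < out.cost


def test_strategy_outcomes_directions_and_bounds(dmmr_eval, pmmr_eval):
    for ev in (dmmr_eval, pmmr_eval):
        dcp, cp = ev.evaluate("DCP"), ev.evaluate("CP")
        assert dcp.cost > cp.cost  # combination therapy costs more
        assert dcp.qaly > cp.qaly  # and yields more QALYs
        for out in (dcp, cp):
            assert 0 < out.qaly < 18.0 * 0.817  # horizon x max utility
            assert out.cost > 0


def test_maintenance_only_while_progression_free(dmmr_scenario):
    """Maintenance dostarlimab is weighted by PFS occupancy: a faster
    progressing cohort must spend less on it."""
    slow = StrategyEvaluator(dmmr_scenario)
    fast_models = {
        "DCP": {
            "pfs": SurvivalModel("exponential", {"rate": 0.3}),
            "os": dmmr_scenario.models["DCP"]["os"],
        },
        "CP": dmmr_scenario.models["CP"],
    }
    fast_sc = dataclasses.replace(dmmr_scenario, models=fast_models)
    fast = StrategyEvaluator(fast_sc)
    assert fast._arm["DCP"]["w_maintenance"] < slow._arm["DCP"]["w_maintenance"]
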