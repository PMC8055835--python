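"""Partitioned survival model: membership, dosing arithmetic, costs, QALYs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from psmcure import (
    CycleGrid,
    EconomicInputs,
    compute_membership,
    expected_costs,
    expected_qalys_lys,
    regimen_cycle_cost,
    run_arm,
)
from psmcure.ps_model import CONTROL, INTERVENTION, StateOccupancy, second_line_lump_cost


def _ones_grid(grid):
    return np.ones(grid.n_cycles)


def _no_ae_inputs(econ):
    overrides = {}
    for ae in econ.ae_names():
        overrides[f"adverse_events.{ae}.risk_intervention"] = 0.0
        overrides[f"adverse_events.{ae}.risk_control"] = 0.0
    return econ.with_overrides(overrides)


class TestCycleGrid:
    def test_44_cycles_cover_the_horizon(self):
        grid = CycleGrid()
        assert grid.n_cycles == 44
        assert grid.n_cycles * 21 >= 2.5 * 365.25

    def test_discount_factor_closed_form(self):
        grid = CycleGrid()
        d = (1.03) ** (-1.0)
        t_days = np.array([365.25])
        got = (1.0 + 0.03) ** (-(t_days / 365.25))
        assert got[0] == pytest.approx(1 / 1.03)
        # first cycle is undiscounted
        assert grid.discount_factors()[0] == 1.0

    def test_discount_rate_bounds_enforced(self):
        with pytest.raises(ValueError):
            CycleGrid(discount_rate_annual=0.07)


class TestMembership:
    def test_equal_curves_no_postprogression(self):
        grid = CycleGrid()
        s = np.linspace(1, 0.2, grid.n_cycles)
        occ = compute_membership(s, s, grid)
        assert np.allclose(occ.pp, 0.0)

    def test_definition_point(self):
        grid = CycleGrid()
        s_os = np.full(grid.n_cycles, 0.8)
        s_pfs = np.full(grid.n_cycles, 0.5)
        s_os[0] = s_pfs[0] = 1.0
        occ = compute_membership(s_os, s_pfs, grid)
        assert (occ.pf[1], occ.pp[1], occ.dead[1]) == (0.5, pytest.approx(0.3), pytest.approx(0.2))

    def test_pfs_above_os_is_clamped(self):
        grid = CycleGrid()
        s_os = np.linspace(1, 0.1, grid.n_cycles)
        s_pfs = np.minimum(s_os + 0.05, 1.0)  # crosses above OS
        occ = compute_membership(s_os, s_pfs, grid)
        assert np.allclose(occ.pf, s_os)
        assert np.allclose(occ.pp, 0.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_conservation_property(self, seed):
        grid = CycleGrid()
        rng = np.random.default_rng(seed)
        s_os = np.concatenate([[1.0], np.sort(rng.uniform(0, 1, grid.n_cycles - 1))[::-1]])
        s_pfs = s_os * np.concatenate([[1.0], np.sort(rng.uniform(0, 1, grid.n_cycles - 1))[::-1]])
        occ = compute_membership(s_os, s_pfs, grid)
        assert np.max(np.abs(occ.pf + occ.pp + occ.dead - 1.0)) <= 1e-9

    def test_curve_outside_unit_interval_rejected(self):
        grid = CycleGrid()
        s = np.ones(grid.n_cycles)
        bad = s.copy()
        bad[3] = 1.2
        with pytest.raises(ValueError):
            compute_membership(bad, s, grid)


class TestRegimenCosts:
    def test_atezolizumab_cycle_cost(self, econ):
        # 1,200 mg at 77.46 per 10 mg
        cost = regimen_cycle_cost("atezolizumab", econ)
        assert cost["atezolizumab"] == pytest.approx(9295.20)

    def test_carboplatin_calvert_dose_cost(self, econ):
        # AUC 5 · (70 + 25) = 475 mg at 3.09 per 50 mg
        cost = regimen_cycle_cost("carboplatin_etoposide", econ)
        assert cost["carboplatin"] == pytest.approx(29.355)

    def test_etoposide_cycle_cost(self, econ):
        # 100 mg/m² · 1.86 m² · 3 days at 0.66 per 10 mg
        cost = regimen_cycle_cost("carboplatin_etoposide", econ)
        assert cost["etoposide"] == pytest.approx(558 * 0.066)

    def test_vincristine_flat_dose(self, econ):
        cost = regimen_cycle_cost("cav", econ)
        assert cost["vincristine"] == pytest.approx(9.76)

    def test_topotecan_five_day_course(self, econ):
        # 1.5 mg/m² · 1.86 · 5 days at 0.94 per 0.1 mg
        cost = regimen_cycle_cost("topotecan", econ)
        assert cost["topotecan"] == pytest.approx(1.5 * 1.86 * 5 / 0.1 * 0.94)

    def test_unknown_regimen_rejected(self, econ):
        with pytest.raises(ValueError):
            regimen_cycle_cost("cisplatin", econ)

    def test_second_line_uptake_weighting(self, econ):
        topo = sum(regimen_cycle_cost("topotecan", econ).values())
        cav = sum(regimen_cycle_cost("cav", econ).values())
        expected = 4 * (0.403 * topo + 0.154 * cav)
        assert second_line_lump_cost(econ, INTERVENTION) == pytest.approx(expected)


class TestExpectedCosts:
    def test_cost_doubles_when_all_prices_double(self, econ):
        grid = CycleGrid()
        s_os = np.linspace(1, 0.05, grid.n_cycles)
        s_pfs = s_os * np.linspace(1, 0.3, grid.n_cycles)
        occ = compute_membership(s_os, s_pfs, grid)
        base = expected_costs(occ, econ, grid, INTERVENTION)
        cost_names = [n for n in econ.uncertain_params() if "cost" in n or "admin" in n]
        doubled = econ.with_overrides({n: 2 * econ.value(n) for n in cost_names})
        twice = expected_costs(occ, doubled, grid, INTERVENTION)
        assert twice["total"] == pytest.approx(2 * base["total"])

    def test_immediate_extinction_leaves_first_cycle_costs(self, econ):
        # cohort all dead after cycle 0: only cycle-1 treatment, supportive,
        # AE, plus the terminal second-line/death flows remain
        grid = CycleGrid()
        s_os = np.zeros(grid.n_cycles)
        s_os[0] = 1.0
        occ = compute_membership(s_os, s_os, grid)
        costs = expected_costs(occ, econ, grid, CONTROL)
        chemo = sum(regimen_cycle_cost("carboplatin_etoposide", econ).values())
        assert costs["chemotherapy"] == pytest.approx(chemo)
        assert costs["administration"] == pytest.approx(econ.value("other_costs.admin_first"))
        assert costs["supportive_care"] == pytest.approx(478.0)
        d1 = grid.discount_factors()[1]
        assert costs["death"] == pytest.approx(d1 * econ.value("other_costs.death"))

    def test_atezolizumab_only_in_intervention_arm(self, econ):
        grid = CycleGrid()
        s = np.linspace(1, 0.1, grid.n_cycles)
        occ = compute_membership(s, s, grid)
        assert expected_costs(occ, econ, grid, CONTROL)["atezolizumab"] == 0.0
        assert expected_costs(occ, econ, grid, INTERVENTION)["atezolizumab"] > 0.0


class TestQalysLys:
    def test_one_perfect_pf_year(self, econ):
        # 10 cycles of 36.525 days = exactly one year, everyone PF, no
        # discounting, no adverse events: 0.84 QALYs and 1.0 life-year
        grid = CycleGrid(cycle_length_days=36.525, horizon_years=1.0, discount_rate_annual=0.0)
        assert grid.n_cycles == 10
        inputs = _no_ae_inputs(econ).with_overrides({"discount_rate": 0.0})
        occ = StateOccupancy(pf=_ones_grid(grid), pp=np.zeros(grid.n_cycles),
                             dead=np.zeros(grid.n_cycles))
        qaly, lyg = expected_qalys_lys(occ, inputs, grid, CONTROL)
        assert lyg == pytest.approx(1.0)
        assert qaly == pytest.approx(0.84)

    def test_unit_utilities_make_qalys_equal_lys(self, econ):
        grid = CycleGrid()
        inputs = _no_ae_inputs(econ).with_overrides(
            {"utilities.pf": 1.0, "utilities.pp": 1.0}
        )
        s_os = np.linspace(1, 0.2, grid.n_cycles)
        occ = compute_membership(s_os, s_os * 0.6, grid)
        qaly, lyg = expected_qalys_lys(occ, inputs, grid, CONTROL)
        assert qaly == pytest.approx(lyg)

    def test_anemia_decrement_arithmetic(self, econ):
        # risk 0.14 × disutility 0.09 × 21 days ≈ 0.000724 QALYs
        grid = CycleGrid()
        occ = StateOccupancy(pf=_ones_grid(grid), pp=np.zeros(grid.n_cycles),
                             dead=np.zeros(grid.n_cycles))
        none = _no_ae_inputs(econ)
        anemia_only = none.with_overrides(
            {"adverse_events.anemia.risk_intervention": 0.14}
        )
        q0, _ = expected_qalys_lys(occ, none, grid, INTERVENTION)
        q1, _ = expected_qalys_lys(occ, anemia_only, grid, INTERVENTION)
        assert q0 - q1 == pytest.approx(0.14 * 0.09 * 21 / 365.25, rel=1e-6)

    def test_discounting_reduces_totals(self, econ):
        grid = CycleGrid()
        s_os = np.linspace(1, 0.2, grid.n_cycles)
        occ = compute_membership(s_os, s_os * 0.7, grid)
        q_disc, l_disc = expected_qalys_lys(occ, econ, grid, CONTROL)
        undisc = econ.with_overrides({"discount_rate": 0.0})
        q_0, l_0 = expected_qalys_lys(occ, undisc, grid, CONTROL)
        assert q_disc < q_0 and l_disc < l_0

    def test_higher_pf_utility_strictly_increases_qalys(self, econ):
        grid = CycleGrid()
        s_os = np.linspace(1, 0.2, grid.n_cycles)
        occ = compute_membership(s_os, s_os * 0.7, grid)
        q_lo, _ = expected_qalys_lys(occ, econ, grid, CONTROL)
        q_hi, _ = expected_qalys_lys(
            occ, econ.with_overrides({"utilities.pf": 0.883}), grid, CONTROL
        )
        assert q_hi > q_lo

    def test_utility_outside_unit_interval_rejected(self, econ):
        with pytest.raises(ValueError):
            econ.with_overrides({"utilities.pf": 1.4})


class TestEconomicInputs:
    def test_unknown_override_rejected(self, econ):
        with pytest.raises(KeyError):
            econ.with_overrides({"utilities.nonexistent": 0.5})

    def test_bounds_must_bracket_value(self, econ):
        import copy

        raw = copy.deepcopy(econ.raw)
        raw["utilities"]["pf"]["value"] = 0.99  # above its high bound
        with pytest.raises(ValueError):
            EconomicInputs(raw)

    def test_half_cycle_grid_changes_membership_times(self, econ):
        plain, half = CycleGrid(), CycleGrid(half_cycle=True)
        assert np.allclose(half.eval_times_days - plain.eval_times_days, 10.5)

    def test_run_arm_totals_consistent(self, econ):
        grid = CycleGrid()
        s_os = np.linspace(1, 0.05, grid.n_cycles)
        s_pfs = s_os * np.linspace(1, 0.3, grid.n_cycles)
        arm = run_arm(s_os, s_pfs, econ, grid, INTERVENTION)
        assert arm.total_cost == pytest.approx(
            sum(v for k, v in arm.costs.items() if k != "total")
        )
        assert 0 < arm.qalys < arm.lygs
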