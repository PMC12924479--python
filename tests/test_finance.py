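import dataclasses

import numpy as np
import pytest

from preventure.finance import (
    annual_costs,
    project,
    projection_frame,
    staffing_plan,
    unit_economics,
    write_projection,
)
from preventure.market import UserTrajectory, simulate_users
from preventure.parameters import ScenarioParameters
from preventure.sampling import RandomStream, sample_scenario


def scenario_with(base, **changes):
    values = dict(base.values)
    values.update(changes)
    return ScenarioParameters(values=values, run=base.run)


def flat_trajectory(active_by_year):
    arr = np.asarray(active_by_year, dtype=float)
    return UserTrajectory(new=arr.copy(), active=arr)


class TestStaffing:
    def test_small_user_base_runs_on_one_of_each(self, base_scenario):
        plan = staffing_plan(flat_trajectory([639.0] * 7), base_scenario)
        assert np.all(plan.technicians == 1) and np.all(plan.managers == 1)

    def test_year7_scale_needs_five_technicians_one_manager(self, base_scenario):
        plan = staffing_plan(flat_trajectory([2917.0] * 7), base_scenario)
        assert np.all(plan.technicians == 5)  # ceil(2917/700)
        assert np.all(plan.managers == 1)  # ceil(5/15)

    def test_zero_users_keeps_minimum_staff(self, base_scenario):
        plan = staffing_plan(flat_trajectory([0.0] * 7), base_scenario)
        assert np.all(plan.technicians == 1) and np.all(plan.managers == 1)


class TestAnnualCosts:
    def test_five_technician_salary_bill(self, base_scenario):
        traj = flat_trajectory([2917.0] * 7)
        costs = annual_costs(base_scenario, traj, staffing_plan(traj, base_scenario), 7)
        assert costs.technician_salaries == pytest.approx(5 * 95_000)

    def test_user_scaled_lines_year1(self, base_scenario):
        traj = flat_trajectory([639.0] * 7)
        costs = annual_costs(base_scenario, traj, staffing_plan(traj, base_scenario), 1)
        assert costs.acquisition == pytest.approx(639 * 220)
        assert costs.call_center == pytest.approx(639 * 20)
        assert costs.backend == pytest.approx(639 * 35)

    def test_fixed_base_with_zero_users(self, base_scenario):
        """Year 2 with no users: salaries + office + maintenance + compliance."""
        traj = flat_trajectory([0.0] * 7)
        costs = annual_costs(base_scenario, traj, staffing_plan(traj, base_scenario), 2)
        assert costs.total == pytest.approx(95_000 + 120_000 + 2 * 11_200 + 50_000 + 25_000)

    def test_one_time_outlays_only_in_year1(self, base_scenario):
        traj = flat_trajectory([100.0] * 7)
        plan = staffing_plan(traj, base_scenario)
        y1 = annual_costs(base_scenario, traj, plan, 1)
        y2 = annual_costs(base_scenario, traj, plan, 2)
        assert y1.app_development == pytest.approx(300_000) and y1.ce_mdr == pytest.approx(20_000)
        assert y2.app_development == 0 and y2.ce_mdr == 0
        assert y1.app_maintenance == y2.app_maintenance == pytest.approx(50_000)

    def test_year0_booking_removes_outlays_from_ledger(self, base_scenario):
        run = dataclasses.replace(base_scenario.run, upfront_cost_year=0)
        traj = simulate_users(base_scenario.values, run)
        costs = annual_costs(base_scenario.values, traj, staffing_plan(traj, base_scenario), 1, run)
        assert costs.app_development == 0 and costs.ce_mdr == 0


class TestProjection:
    def test_free_product_never_breaks_even(self, base_scenario):
        proj = project(scenario_with(base_scenario, price_monthly=0.0))
        assert np.all(proj.net_cash_flow < 0)
        assert proj.breakeven_year is None

    def test_zero_cost_positive_revenue_breaks_even_immediately(self, base_scenario):
        cost_params = (
            "cac", "technician_salary", "manager_salary",
            "office_supplies_per_worker", "office_rent_per_worker",
            "call_center_per_user", "backend_per_user", "app_development",
            "app_maintenance", "ce_mdr_certification", "revfadp_compliance",
        )
        zeroed = {
            k: (0.0 if k in cost_params else v) for k, v in base_scenario.values.items()
        }
        proj = project(ScenarioParameters(values=zeroed, run=base_scenario.run))
        assert proj.breakeven_year == 1

    def test_ledger_identities_on_random_scenarios(self, table2):
        """Revenue, cost-total and cumulative-sum identities hold exactly."""
        stream = RandomStream(77, "ledger")
        for _ in range(20):
            sp = sample_scenario(table2, stream)
            proj = project(sp)
            assert np.allclose(
                proj.revenue, proj.trajectory.active * sp["price_monthly"] * 12, rtol=0, atol=1e-9
            )
            total = sum(
                getattr(proj.costs, name)
                for name in (
                    "acquisition technician_salaries manager_salaries office "
                    "call_center backend app_development app_maintenance ce_mdr revfadp"
                ).split()
            )
            assert np.array_equal(proj.costs.total, total)
            assert np.allclose(proj.net_cash_flow, proj.revenue - proj.costs.total, rtol=0)
            assert np.allclose(proj.cumulative_cash_flow, np.cumsum(proj.net_cash_flow), rtol=0)

    def test_breakeven_year_definition(self, base_scenario):
        proj = project(base_scenario)
        cum = proj.cumulative_cash_flow
        if np.all(cum < 0):
            assert proj.breakeven_year is None
        else:
            t = proj.breakeven_year
            assert cum[t - 1] >= 0 and np.all(cum[: t - 1] < 0)

    def test_total_cost_non_decreasing_in_users(self, base_scenario):
        lo = project(scenario_with(base_scenario, screening_participation=0.05))
        hi = project(scenario_with(base_scenario, screening_participation=0.15))
        assert np.all(hi.costs.total >= lo.costs.total)

    def test_deterministic_given_scenario(self, base_scenario):
        a, b = project(base_scenario), project(base_scenario)
        assert np.array_equal(a.cumulative_cash_flow, b.cumulative_cash_flow)


class TestUnitEconomics:
    def test_ltv_and_ltv_to_cac_at_medians(self, base_scenario):
        ue = unit_economics(project(base_scenario), base_scenario)
        assert ue["ltv"] == pytest.approx(40 * 12 * 1.5)
        assert ue["ltv_to_cac"] == pytest.approx(720 / 220)

    def test_economies_of_scale_at_medians(self, base_scenario):
        ue = unit_economics(project(base_scenario), base_scenario)
        cpu = ue["cost_per_active_user"]
        assert cpu[-1] < cpu[0]

    def test_zero_active_reports_nan_not_error(self, base_scenario):
        sp = scenario_with(base_scenario, adoption_rate=0.0)
        ue = unit_economics(project(sp), sp)
        assert np.all(np.isnan(ue["cost_per_active_user"]))

    def test_user_scaled_cost_component_linearity(self, base_scenario):
        base = project(base_scenario)
        doubled = project(
            scenario_with(
                base_scenario,
                call_center_per_user=40.0,
                backend_per_user=70.0,
            )
        )
        extra = doubled.costs.total - base.costs.total
        expected = base.costs.call_center + base.costs.backend
        assert np.allclose(extra, expected)


class TestExport:
    def test_frame_shape_and_columns(self, base_scenario):
        frame = projection_frame(project(base_scenario))
        assert len(frame) == 7
        for col in ("year", "active_users", "revenue", "cost_total",
                    "net_cash_flow", "cumulative_cash_flow"):
            assert col in frame.columns

    def test_csv_json_round_trip(self, base_scenario, tmp_path):
        import json

        import pandas as pd

        proj = project(base_scenario)
        write_projection(proj, tmp_path / "p.csv", tmp_path / "p.json")
        frame = pd.read_csv(tmp_path / "p.csv")
        assert np.allclose(frame["cumulative_cash_flow"], proj.cumulative_cash_flow)
        doc = json.loads((tmp_path / "p.json").read_text())
        assert len(doc["ledger"]) == 7
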