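"""Pro forma ledger: revenue, cost breakdown, net/cumulative cash flow, breakeven.

Revenue is subscription income on the year-end paying stock (price x 12).
Costs split into user-scaled lines (acquisition, call-center, backend),
headcount lines driven by a ceiling staffing rule with a minimum of one
technician and one manager, per-worker office costs, recurring compliance and
maintenance, and one-time launch outlays (app build, device certification)
booked in Year 1 by default.  No taxes, depreciation, financing costs or
inflation are modelled.

Everything broadcasts over Monte Carlo batches: parameter values and ledger
columns may be scalars/(T,) vectors or (n,)/(T, n) arrays.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .market import UserTrajectory, simulate_users
from .parameters import RunSettings, ScenarioParameters

__all__ = [
    "StaffingPlan",
    "CostBreakdown",
    "Projection",
    "staffing_plan",
    "annual_costs",
    "project",
    "unit_economics",
    "projection_frame",
    "write_projection",
]

COST_COMPONENTS = (
    "acquisition",
    "technician_salaries",
    "manager_salaries",
    "office",
    "call_center",
    "backend",
    "app_development",
    "app_maintenance",
    "ce_mdr",
    "revfadp",
)


@dataclass(frozen=True)
class StaffingPlan:
    """Integer FTE counts per year; floors of one technician and one manager."""

    technicians: np.ndarray
    managers: np.ndarray


@dataclass(frozen=True)
class CostBreakdown:
    """Per-year cost lines (CHF); ``total`` is their exact sum."""

    acquisition: np.ndarray
    technician_salaries: np.ndarray
    manager_salaries: np.ndarray
    office: np.ndarray
    call_center: np.ndarray
    backend: np.ndarray
    app_development: np.ndarray
    app_maintenance: np.ndarray
    ce_mdr: np.ndarray
    revfadp: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return sum(getattr(self, name) for name in COST_COMPONENTS)


@dataclass(frozen=True)
class Projection:
    """The full per-scenario ledger over the horizon."""

    trajectory: UserTrajectory
    staffing: StaffingPlan
    revenue: np.ndarray
    costs: CostBreakdown
    net_cash_flow: np.ndarray
    cumulative_cash_flow: np.ndarray
    breakeven_year: int | None  # plain operating cumulative position

    @property
    def horizon(self) -> int:
        return self.revenue.shape[0]


def _values(sp) -> Mapping:
    return sp.values if isinstance(sp, ScenarioParameters) else sp


def staffing_plan(trajectory: UserTrajectory, sp: ScenarioParameters | Mapping) -> StaffingPlan:
    """technicians = max(1, ceil(active / users-per-technician));
    managers = max(1, ceil(technicians / technicians-per-manager))."""
    v = _values(sp)
    tech = np.maximum(1.0, np.ceil(trajectory.active / np.asarray(v["technician_per_user_ratio"], dtype=float)))
    mgr = np.maximum(1.0, np.ceil(tech / np.asarray(v["manager_per_technician_ratio"], dtype=float)))
    return StaffingPlan(technicians=tech, managers=mgr)


def annual_costs(
    sp: ScenarioParameters | Mapping,
    trajectory: UserTrajectory,
    staffing: StaffingPlan,
    year: int,
    run: RunSettings | None = None,
) -> CostBreakdown:
    """Cost breakdown for one year (1-based)."""
    if run is None:
        if not isinstance(sp, ScenarioParameters):
            raise TypeError("run settings required when passing a bare mapping")
        run = sp.run
    if not (1 <= year <= run.horizon_years):
        raise ValueError(f"year {year} outside horizon 1..{run.horizon_years}")
    v = _values(sp)
    i = year - 1
    new, active = trajectory.new[i], trajectory.active[i]
    tech, mgr = staffing.technicians[i], staffing.managers[i]
    workers = tech + mgr
    # upfront_cost_year == 0 books launch outlays before the ledger starts,
    # so they appear in no in-horizon year
    upfront = 1.0 if (run.upfront_cost_year == 1 and year == 1) else 0.0
    zeros = np.zeros_like(np.asarray(active, dtype=float))
    return CostBreakdown(
        acquisition=new * v["cac"],
        technician_salaries=tech * v["technician_salary"],
        manager_salaries=mgr * v["manager_salary"],
        office=workers * (np.asarray(v["office_supplies_per_worker"], dtype=float) + v["office_rent_per_worker"]),
        call_center=active * v["call_center_per_user"],
        backend=active * v["backend_per_user"],
        app_development=np.asarray(v["app_development"], dtype=float) * upfront + zeros,
        app_maintenance=np.asarray(v["app_maintenance"], dtype=float) + zeros,
        ce_mdr=np.asarray(v["ce_mdr_certification"], dtype=float) * upfront + zeros,
        revfadp=np.asarray(v["revfadp_compliance"], dtype=float) + zeros,
    )


def _stack_costs(per_year: list[CostBreakdown]) -> CostBreakdown:
    return CostBreakdown(
        **{
            f.name: np.stack(np.broadcast_arrays(*[getattr(c, f.name) for c in per_year]))
            for f in fields(CostBreakdown)
        }
    )


def project(sp: ScenarioParameters | Mapping, run: RunSettings | None = None) -> Projection:
    """Run the whole pipeline for one scenario (or a batch mapping)."""
    if run is None:
        if not isinstance(sp, ScenarioParameters):
            raise TypeError("run settings required when passing a bare mapping")
        run = sp.run
    v = _values(sp)
    traj = simulate_users(v, run)
    staff = staffing_plan(traj, v)
    costs = _stack_costs(
        [annual_costs(v, traj, staff, year, run) for year in range(1, run.horizon_years + 1)]
    )
    revenue = traj.active * np.asarray(v["price_monthly"], dtype=float) * 12.0
    net = revenue - costs.total
    cum = np.cumsum(net, axis=0)
    breakeven = _first_breakeven_year(cum)
    return Projection(
        trajectory=traj,
        staffing=staff,
        revenue=revenue,
        costs=costs,
        net_cash_flow=net,
        cumulative_cash_flow=cum,
        breakeven_year=breakeven,
    )


def _first_breakeven_year(cum: np.ndarray):
    """First year with cumulative cash flow >= 0.

    Scalar trajectories return an int or None; batches return an int array
    with 0 standing for 'never'.
    """
    hit = cum >= 0.0
    if cum.ndim == 1:
        idx = np.flatnonzero(hit)
        return int(idx[0]) + 1 if idx.size else None
    return np.where(hit.any(axis=0), hit.argmax(axis=0) + 1, 0)


def unit_economics(projection: Projection, sp: ScenarioParameters | Mapping) -> dict:
    """Scale diagnostics: cost per active user per year, LTV, LTV/CAC.

    Years with no active users report NaN cost-per-user rather than raising.
    Customer lifetime enters only here (the cohort recursion is churn-driven).
    """
    v = _values(sp)
    active = projection.trajectory.active
    with np.errstate(divide="ignore", invalid="ignore"):
        cost_per_user = np.where(active > 0, projection.costs.total / active, np.nan)
    ltv = float(np.asarray(v["price_monthly"]).mean()) * 12.0 * float(
        np.asarray(v["customer_lifetime_years"]).mean()
    )
    cac = float(np.asarray(v["cac"]).mean())
    return {
        "cost_per_active_user": cost_per_user,
        "ltv": ltv,
        "ltv_to_cac": ltv / cac if cac > 0 else np.nan,
    }


def projection_frame(projection: Projection) -> pd.DataFrame:
    """Tidy one-row-per-year ledger (single-scenario projections only)."""
    if projection.revenue.ndim != 1:
        raise ValueError("projection_frame expects a single-scenario projection")
    T = projection.horizon
    data = {
        "year": np.arange(1, T + 1),
        "new_users": projection.trajectory.new,
        "active_users": projection.trajectory.active,
        "technicians": projection.staffing.technicians.astype(int),
        "managers": projection.staffing.managers.astype(int),
        "revenue": projection.revenue,
    }
    for name in COST_COMPONENTS:
        data[f"cost_{name}"] = getattr(projection.costs, name)
    data["cost_total"] = projection.costs.total
    data["net_cash_flow"] = projection.net_cash_flow
    data["cumulative_cash_flow"] = projection.cumulative_cash_flow
    return pd.DataFrame(data)


def write_projection(projection: Projection, csv_path: str | Path, json_path: str | Path | None = None) -> None:
    frame = projection_frame(projection)
    frame.to_csv(csv_path, index=False)
    if json_path is not None:
        payload = frame.to_dict(orient="records")
        doc = {
            "breakeven_year": projection.breakeven_year,
            "ledger": payload,
        }
        Path(json_path).write_text(json.dumps(doc, indent=2, default=float), encoding="utf-8")
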