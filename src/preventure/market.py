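"""Market funnel and paying-user cohort dynamics.

The addressable screening pool is a product of epidemiological stages:

    adults -> eligible -> impaired-fasting-glucose -> undiagnosed -> reachable

Yearly acquisition converts the reachable pool through a digital uptake rate
and a paid-conversion rate; the acquisition cadence factor (default 12)
reflects a monthly uptake opportunity on an annually-quoted funnel.  The
acquisition flow then grows along a concave ramp — a venture's reach compounds
through channels and word of mouth but decelerates as the easy segment is
absorbed — while the paying stock follows the standard cohort recursion

    active_1 = new_1,     active_t = active_{t-1} * (1 - churn) + new_t.

All functions broadcast: parameter values may be scalars (one scenario) or
equal-length numpy arrays (a Monte Carlo batch).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .parameters import RunSettings, ScenarioParameters

__all__ = [
    "FunnelStages",
    "UserTrajectory",
    "funnel_stages",
    "adoption_ramp_multiplier",
    "yearly_new_users",
    "simulate_users",
]


@dataclass(frozen=True)
class FunnelStages:
    """Population counts at each funnel stage (persons; reals, not integers)."""

    adults: np.ndarray | float
    eligible: np.ndarray | float
    ifg: np.ndarray | float
    undiagnosed_ifg: np.ndarray | float
    screened_pool: np.ndarray | float  # persons reachable per year


@dataclass(frozen=True)
class UserTrajectory:
    """Per-year acquisition flow and period-end paying stock.

    ``new`` and ``active`` have shape (T,) for a single scenario or (T, n)
    for a batch; year t is row t-1.
    """

    new: np.ndarray
    active: np.ndarray

    @property
    def horizon(self) -> int:
        return self.new.shape[0]


def _values(sp) -> Mapping:
    return sp.values if isinstance(sp, ScenarioParameters) else sp


def funnel_stages(sp: ScenarioParameters | Mapping) -> FunnelStages:
    v = _values(sp)
    adults = np.asarray(v["adult_population"], dtype=float)
    eligible = adults * v["screening_eligibility"]
    ifg = eligible * v["ifg_prevalence"]
    undiag = ifg * v["undiagnosed_fraction"]
    pool = undiag * v["screening_participation"]
    return FunnelStages(adults, eligible, ifg, undiag, pool)


def adoption_ramp_multiplier(year: int, run: RunSettings) -> float:
    """Growth multiplier applied to the Year-1 acquisition flow.

    ``log``:    1 + strength * ln(t)   (concave; calibrated default)
    ``linear``: 1 + strength * (t - 1)
    ``none``:   1
    """
    t = float(year)
    if run.adoption_ramp_shape == "log":
        return 1.0 + run.adoption_ramp_strength * np.log(t)
    if run.adoption_ramp_shape == "linear":
        return 1.0 + run.adoption_ramp_strength * (t - 1.0)
    return 1.0


def yearly_new_users(sp: ScenarioParameters | Mapping, year: int, run: RunSettings | None = None):
    """New paying users acquired in a given year.

    new_t = reachable pool x adoption rate x paid conversion
            x cadence factor x ramp multiplier(t)
    """
    if run is None:
        if not isinstance(sp, ScenarioParameters):
            raise TypeError("run settings required when passing a bare mapping")
        run = sp.run
    if not (1 <= year <= run.horizon_years):
        raise ValueError(f"year {year} outside horizon 1..{run.horizon_years}")
    v = _values(sp)
    pool = funnel_stages(sp).screened_pool
    base = pool * v["adoption_rate"] * v["paid_conversion"] * run.acquisition_cadence_factor
    return base * adoption_ramp_multiplier(year, run)


def simulate_users(sp: ScenarioParameters | Mapping, run: RunSettings | None = None) -> UserTrajectory:
    """Simulate the full user trajectory over the horizon.

    Satisfies the recursion exactly, hence the closed form
    active_t = sum_{k<=t} new_k * (1 - churn)^(t-k); new cohorts are not
    churned within their first year.
    """
    if run is None:
        if not isinstance(sp, ScenarioParameters):
            raise TypeError("run settings required when passing a bare mapping")
        run = sp.run
    v = _values(sp)
    T = run.horizon_years
    churn = np.asarray(v["churn_rate"], dtype=float)
    new_rows = [np.asarray(yearly_new_users(sp, t, run), dtype=float) for t in range(1, T + 1)]
    new = np.stack(np.broadcast_arrays(*new_rows)) if T > 1 else np.asarray(new_rows)
    active = np.empty_like(new)
    active[0] = new[0]
    for t in range(1, T):
        active[t] = active[t - 1] * (1.0 - churn) + new[t]
    return UserTrajectory(new=new, active=active)
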