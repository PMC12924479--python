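"""Monte Carlo propagation of parameter uncertainty.

Each of the n iterations draws one value per parameter (held constant across
all years of that iteration), runs the pro forma ledger, and values the
resulting cash-flow vector.  From the per-iteration records the module derives
the breakeven-year probability distribution, percentile summaries of NPV/IRR
and user counts, and the a-priori viability verdict.

Breakeven convention.  "Breakeven by year t" is the event that the venture's
cumulative position first reaches zero in year t, so the yearly probabilities
plus P(never) sum to one exactly.  By default the horizon-year position
includes the terminal (exit) value — the venture has broken even at the
horizon if its cumulative operating flows plus what the business would fetch
at the earnings multiple cover the money sunk.  Set
``breakeven_includes_terminal: false`` in the run settings for the plain
operating cumulative position (years before the horizon are identical under
both conventions).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import finance, valuation
from .parameters import ParameterSet, median_scenario
from .sampling import RandomStream, sample_batch

__all__ = [
    "MonteCarloResult",
    "BreakevenDistribution",
    "ViabilityCriteria",
    "run_monte_carlo",
    "breakeven_distribution",
    "summarize",
    "viability_verdict",
    "write_monte_carlo",
]

MC_STREAM_LABEL = "monte-carlo"


@dataclass(frozen=True)
class MonteCarloResult:
    """Per-iteration outcomes of the Monte Carlo run.

    ``breakeven_year`` uses 0 for 'never'.  ``irr`` is NaN where the IRR does
    not exist (no sign change of NPV over the search bracket).
    """

    n: int
    horizon: int
    breakeven_year: np.ndarray  # (n,) int, 0 == never
    cumulative_final: np.ndarray  # (n,) CHF, operating (terminal excluded)
    npv: np.ndarray  # (n,) CHF
    irr: np.ndarray  # (n,) fraction, NaN if undefined
    active_users: np.ndarray  # (T, n)
    net_cash_flow: np.ndarray  # (T, n)
    revenue: np.ndarray  # (T, n)
    terminal: np.ndarray  # (n,)
    breakeven_includes_terminal: bool = True

    def __post_init__(self):
        if self.breakeven_year.shape != (self.n,):
            raise ValueError("per-iteration record count must equal n")


@dataclass(frozen=True)
class BreakevenDistribution:
    p_year: np.ndarray  # (T,) probability of first breakeven in year t
    p_never: float

    @property
    def p_any(self) -> float:
        return float(self.p_year.sum())

    def p_by_year(self, year: int) -> float:
        return float(self.p_year[:year].sum())

    @property
    def modal_year(self) -> int:
        """Year with the largest single-year probability (1-based)."""
        return int(np.argmax(self.p_year)) + 1


@dataclass(frozen=True)
class ViabilityCriteria:
    """A-priori investment thresholds: (i) median IRR at or above the hurdle,
    (ii) breakeven by the stated year at or above the stated probability,
    (iii) positive NPV at the median scenario."""

    irr_hurdle: float = 0.20
    breakeven_year_limit: int = 5
    breakeven_probability_threshold: float = 0.50
    npv_threshold: float = 0.0


def run_monte_carlo(pset: ParameterSet, stream: RandomStream | None = None) -> MonteCarloResult:
    """Sample, project and value ``pset.run.n_iterations`` scenarios.

    Deterministic given the seed: the default stream is keyed on
    ``pset.run.seed``.
    """
    run = pset.run
    if stream is None:
        stream = RandomStream(seed=run.seed, label=MC_STREAM_LABEL)
    batch = sample_batch(pset, stream, run.n_iterations)
    proj = finance.project(batch, run)
    net = proj.net_cash_flow
    terminal = run.terminal_multiple * net[-1]
    disc = batch["discount_rate"]
    t = np.arange(1, run.horizon_years + 1)[:, None]
    cf = net.copy()
    cf[-1] += terminal
    npv = (cf / (1.0 + disc)[None, :] ** t).sum(axis=0)
    irr = valuation.irr_batch(net, terminal)
    be_cum = proj.cumulative_cash_flow.copy()
    if run.breakeven_includes_terminal:
        be_cum[-1] += terminal
    hit = be_cum >= 0.0
    breakeven = np.where(hit.any(axis=0), hit.argmax(axis=0) + 1, 0)
    return MonteCarloResult(
        n=run.n_iterations,
        horizon=run.horizon_years,
        breakeven_year=breakeven,
        cumulative_final=proj.cumulative_cash_flow[-1],
        npv=npv,
        irr=irr,
        active_users=proj.trajectory.active,
        net_cash_flow=net,
        revenue=proj.revenue,
        terminal=terminal,
        breakeven_includes_terminal=run.breakeven_includes_terminal,
    )


def breakeven_distribution(mc: MonteCarloResult) -> BreakevenDistribution:
    counts = np.bincount(mc.breakeven_year, minlength=mc.horizon + 1)
    p = counts / mc.n
    return BreakevenDistribution(p_year=p[1:], p_never=float(p[0]))


def summarize(mc: MonteCarloResult, percentiles=(0.025, 0.25, 0.5, 0.75, 0.975)) -> pd.DataFrame:
    """Percentile table (linear interpolation of order statistics) for the
    headline metrics.  Iterations with undefined IRR are excluded from the
    IRR row; their count is reported in the ``n_undefined`` column."""
    qs = np.asarray(percentiles, dtype=float)
    if qs.size == 0 or np.any((qs < 0) | (qs > 1)):
        raise ValueError("percentiles must be probabilities in [0, 1]")
    rows = {}
    metrics = {
        "npv": mc.npv,
        "irr": mc.irr[~np.isnan(mc.irr)],
        "cumulative_cash_flow_final": mc.cumulative_final,
    }
    for year in (1, mc.horizon):
        metrics[f"active_users_year_{year}"] = mc.active_users[year - 1]
    for name, values in metrics.items():
        if values.size == 0:
            raise ValueError(f"no defined values for metric '{name}'")
        rows[name] = {
            **{f"p{100 * q:g}": float(np.quantile(values, q)) for q in qs},
            "n_undefined": mc.n - values.size,
        }
    return pd.DataFrame(rows).T


def viability_verdict(
    mc: MonteCarloResult,
    pset: ParameterSet,
    criteria: ViabilityCriteria = ViabilityCriteria(),
) -> dict:
    """Evaluate the three a-priori criteria; returns measured values and
    booleans per criterion plus the overall verdict."""
    dist = breakeven_distribution(mc)
    defined_irr = mc.irr[~np.isnan(mc.irr)]
    median_irr = float(np.median(defined_irr)) if defined_irr.size else float("nan")
    p_by_limit = dist.p_by_year(criteria.breakeven_year_limit)
    base = finance.project(median_scenario(pset))
    terminal = pset.run.terminal_multiple * float(base.net_cash_flow[-1])
    cfv = valuation.CashFlowVector(base.net_cash_flow, terminal=terminal)
    base_npv = valuation.npv(cfv, float(pset["discount_rate"].median))
    checks = {
        "irr_hurdle": {
            "measured": median_irr,
            "threshold": criteria.irr_hurdle,
            "passed": bool(median_irr >= criteria.irr_hurdle),
        },
        "breakeven_by_year": {
            "measured": p_by_limit,
            "threshold": criteria.breakeven_probability_threshold,
            "year_limit": criteria.breakeven_year_limit,
            "passed": bool(p_by_limit >= criteria.breakeven_probability_threshold),
        },
        "median_scenario_npv": {
            "measured": base_npv,
            "threshold": criteria.npv_threshold,
            "passed": bool(base_npv > criteria.npv_threshold),
        },
    }
    checks["overall"] = all(c["passed"] for c in checks.values())
    return checks


def iteration_frame(mc: MonteCarloResult) -> pd.DataFrame:
    """One row per iteration: breakeven year (0 = never), NPV, IRR, final
    cumulative cash flow, and per-year active users."""
    data = {
        "breakeven_year": mc.breakeven_year,
        "npv": mc.npv,
        "irr": mc.irr,
        "cumulative_cash_flow_final": mc.cumulative_final,
    }
    for year in range(1, mc.horizon + 1):
        data[f"active_users_year_{year}"] = mc.active_users[year - 1]
    return pd.DataFrame(data)


def write_monte_carlo(
    mc: MonteCarloResult,
    pset: ParameterSet,
    csv_path: str | Path,
    summary_path: str | Path | None = None,
    criteria: ViabilityCriteria = ViabilityCriteria(),
) -> None:
    iteration_frame(mc).to_csv(csv_path, index=False)
    if summary_path is not None:
        dist = breakeven_distribution(mc)
        doc = {
            "n_iterations": mc.n,
            "breakeven": {
                "p_year": {str(t + 1): float(p) for t, p in enumerate(dist.p_year)},
                "p_never": dist.p_never,
                "p_any": dist.p_any,
                "modal_year": dist.modal_year,
                "includes_terminal_at_horizon": mc.breakeven_includes_terminal,
            },
            "percentiles": json.loads(summarize(mc).to_json(orient="index")),
            "viability": viability_verdict(mc, pset, criteria),
        }
        Path(summary_path).write_text(json.dumps(doc, indent=2, default=float), encoding="utf-8")
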