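"""One-way tornado analysis and two-way elasticity grids.

The tornado swings each parameter between its min and max while the rest sit
at their medians (deterministic mode) or at their sampled distributions with
common random numbers (Monte Carlo mode), ranking parameters by the induced
NPV swing.  The two-way grids fix a pair of parameters on a lattice, draw all
other parameters from their distributions with common random numbers shared
across cells, and record breakeven probability (or median NPV) per cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import finance, valuation
from .parameters import ParameterSet, median_scenario
from .sampling import RandomStream, sample_batch

__all__ = [
    "TornadoEntry",
    "ElasticityGrid",
    "one_way_tornado",
    "two_way_grid",
    "DEFAULT_PRICE_CHURN_AXES",
    "DEFAULT_CAC_PARTICIPATION_AXES",
]

#: Default lattices mirroring the published heatmaps.
DEFAULT_PRICE_CHURN_AXES = (
    ("price_monthly", (20.0, 30.0, 40.0, 50.0, 60.0)),
    ("churn_rate", (0.40, 0.50, 0.55, 0.60, 0.70)),
)
DEFAULT_CAC_PARTICIPATION_AXES = (
    ("cac", (150.0, 200.0, 250.0, 300.0, 350.0)),
    ("screening_participation", (0.05, 0.10, 0.15)),
)

GRID_STREAM_LABEL = "two-way-grid"
TORNADO_STREAM_LABEL = "tornado"


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    npv_at_min: float
    npv_at_max: float

    @property
    def swing(self) -> float:
        return abs(self.npv_at_max - self.npv_at_min)


@dataclass(frozen=True)
class ElasticityGrid:
    axis1_name: str
    axis1_values: tuple
    axis2_name: str
    axis2_values: tuple
    metric: str
    cells: np.ndarray  # shape (len(axis1), len(axis2))

    def frame(self) -> pd.DataFrame:
        """Long/tidy format: one row per cell."""
        rows = [
            {self.axis1_name: a, self.axis2_name: b, self.metric: self.cells[i, j]}
            for i, a in enumerate(self.axis1_values)
            for j, b in enumerate(self.axis2_values)
        ]
        return pd.DataFrame(rows)


def _median_npv_at(pset: ParameterSet, overrides: dict[str, float]) -> float:
    """Deterministic NPV: overridden values, all else at medians."""
    sp = median_scenario(pset)
    values = dict(sp.values)
    values.update(overrides)
    proj = finance.project(values, pset.run)
    terminal = pset.run.terminal_multiple * float(proj.net_cash_flow[-1])
    cfv = valuation.CashFlowVector(proj.net_cash_flow, terminal=terminal)
    return valuation.npv(cfv, values["discount_rate"])


def _mc_metrics(pset: ParameterSet, overrides: dict[str, float], n: int, seed: int) -> dict:
    """Breakeven probability and median NPV with the pinned overrides, all
    other parameters drawn with common random numbers (same seed/label)."""
    run = pset.run
    stream = RandomStream(seed=seed, label=GRID_STREAM_LABEL)
    batch = sample_batch(pset, stream, n, overrides=overrides)
    proj = finance.project(batch, run)
    net = proj.net_cash_flow
    terminal = run.terminal_multiple * net[-1]
    be_cum = proj.cumulative_cash_flow.copy()
    if run.breakeven_includes_terminal:
        be_cum[-1] += terminal
    p_be = float((be_cum >= 0.0).any(axis=0).mean())
    disc = batch["discount_rate"]
    t = np.arange(1, run.horizon_years + 1)[:, None]
    cf = net.copy()
    cf[-1] += terminal
    npv = (cf / (1.0 + disc)[None, :] ** t).sum(axis=0)
    return {"breakeven_probability": p_be, "mc_median_npv": float(np.median(npv))}


def one_way_tornado(
    pset: ParameterSet,
    metric: str = "npv_at_median",
    n_iterations: int = 2000,
    seed: int | None = None,
) -> list[TornadoEntry]:
    """Rank parameters by NPV swing between their min and max.

    ``npv_at_median``: other parameters at medians (deterministic).
    ``mc_median_npv``: other parameters sampled with common random numbers.
    Entries are sorted by swing descending, ties broken by parameter name.
    """
    if metric not in ("npv_at_median", "mc_median_npv"):
        raise ValueError(f"unknown tornado metric '{metric}'")
    seed = pset.run.seed if seed is None else seed
    entries = []
    for name, spec in pset.specs.items():
        lo_hi = []
        for bound in (spec.min, spec.max):
            if metric == "npv_at_median":
                lo_hi.append(_median_npv_at(pset, {name: bound}))
            else:
                lo_hi.append(
                    _mc_metrics(pset, {name: bound}, n_iterations, seed)["mc_median_npv"]
                )
        entries.append(TornadoEntry(parameter=name, npv_at_min=lo_hi[0], npv_at_max=lo_hi[1]))
    return sorted(entries, key=lambda e: (-e.swing, e.parameter))


def two_way_grid(
    pset: ParameterSet,
    param_a: str,
    values_a,
    param_b: str,
    values_b,
    metric: str = "breakeven_probability",
    n_per_cell: int = 2000,
    seed: int | None = None,
) -> ElasticityGrid:
    """Evaluate a metric on the lattice values_a x values_b.

    Non-grid parameters are drawn from their full distributions; the same
    seed and stream label is reused in every cell, so cells differ only
    through the pinned pair (common random numbers).
    """
    for name in (param_a, param_b):
        if name not in pset.specs:
            raise KeyError(
                f"unknown parameter '{name}'; valid names: {sorted(pset.specs)}"
            )
    if metric not in ("breakeven_probability", "mc_median_npv"):
        raise ValueError(f"unknown grid metric '{metric}'")
    seed = pset.run.seed if seed is None else seed
    values_a = tuple(float(v) for v in values_a)
    values_b = tuple(float(v) for v in values_b)
    cells = np.empty((len(values_a), len(values_b)))
    for i, a in enumerate(values_a):
        for j, b in enumerate(values_b):
            m = _mc_metrics(pset, {param_a: a, param_b: b}, n_per_cell, seed)
            cells[i, j] = m[metric]
    return ElasticityGrid(
        axis1_name=param_a,
        axis1_values=values_a,
        axis2_name=param_b,
        axis2_values=values_b,
        metric=metric,
        cells=cells,
    )
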