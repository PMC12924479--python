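"""Discounted cash-flow valuation: NPV with terminal value, IRR by root finding.

Conventions.  Cash flows are end-of-year, with Year 1 discounted one period —
there is no separate t=0 line because the launch outlays already sit in the
Year-1 ledger (Year-0 booking is available via run settings upstream).  The
terminal value, an earnings multiple of the final-year net cash flow, is added
at t = T and discounted accordingly.  IRR is the root of NPV(r) = 0 located by
bracketing and bisection on r in (-0.999, 10]; when several sign changes exist
the smallest root is returned and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CashFlowVector", "ValuationResult", "terminal_value", "npv", "irr", "valuation"]

IRR_BRACKET = (-0.999, 10.0)
IRR_TOL = 1e-8


@dataclass(frozen=True)
class CashFlowVector:
    """Net annual cash flows cf_t for t = 1..T plus a terminal lump at t = T."""

    flows: np.ndarray  # shape (T,)
    terminal: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "flows", np.asarray(self.flows, dtype=float))
        if self.flows.ndim != 1 or self.flows.size == 0:
            raise ValueError("flows must be a non-empty 1-D vector")

    @property
    def horizon(self) -> int:
        return self.flows.size

    def with_terminal_applied(self) -> np.ndarray:
        cf = self.flows.copy()
        cf[-1] += self.terminal
        return cf


@dataclass(frozen=True)
class ValuationResult:
    npv: float
    irr: float | None
    discount_rate: float
    terminal_value: float
    irr_multiple_roots: bool = False


def terminal_value(final_year_earnings: float, multiple: float, floor_at_zero: bool = False) -> float:
    """Exit-value proxy: ``multiple`` x final-year earnings (net cash flow).

    Negative earnings give a negative terminal value by default; set
    ``floor_at_zero`` to clamp at 0 (a venture is abandoned, not sold at a
    negative price).
    """
    if multiple < 0:
        raise ValueError("earnings multiple must be >= 0")
    tv = multiple * final_year_earnings
    return max(tv, 0.0) if floor_at_zero else tv


def npv(cfv: CashFlowVector, rate: float) -> float:
    """Present value of the vector at ``rate``: sum cf_t/(1+r)^t + TV/(1+r)^T."""
    if rate <= -1.0:
        raise ValueError("rate must exceed -1")
    cf = cfv.with_terminal_applied()
    t = np.arange(1, cf.size + 1)
    return float(np.sum(cf / (1.0 + rate) ** t))


def _npv_poly(cf: np.ndarray, rate: float) -> float:
    t = np.arange(1, cf.size + 1)
    return float(np.sum(cf / (1.0 + rate) ** t))


def irr(cfv: CashFlowVector) -> tuple[float | None, bool]:
    """Internal rate of return, or None when no root exists in the bracket.

    Returns ``(root, multiple)`` where ``multiple`` flags additional sign
    changes of NPV beyond the returned (smallest) root.  With a single
    sign change in the cash-flow sequence the root is unique.
    """
    cf = cfv.with_terminal_applied()
    if np.all(cf <= 0) or np.all(cf >= 0):
        return None, False
    lo, hi = IRR_BRACKET
    # dense scan where realistic IRRs live, coarser in the far tail; close
    # root pairs inside one subinterval would go undetected, hence the 0.01
    # resolution on [-1, 1]
    grid = np.concatenate(
        [
            np.linspace(lo, 1.0, 201, endpoint=False),
            np.linspace(1.0, hi, 46),
        ]
    )
    vals = np.array([_npv_poly(cf, r) for r in grid])
    sign = np.sign(vals)
    # exact zeros on the grid count as roots
    zero_idx = np.flatnonzero(vals == 0.0)
    changes = np.flatnonzero(sign[:-1] * sign[1:] < 0)
    roots: list[float] = [float(grid[i]) for i in zero_idx]
    for i in changes:
        a, b = float(grid[i]), float(grid[i + 1])
        fa = vals[i]
        while b - a > IRR_TOL:
            m = 0.5 * (a + b)
            fm = _npv_poly(cf, m)
            if fm == 0.0:
                a = b = m
                break
            if np.sign(fm) == np.sign(fa):
                a, fa = m, fm
            else:
                b = m
        roots.append(0.5 * (a + b))
    if not roots:
        return None, False
    roots.sort()
    return roots[0], len(roots) > 1


def valuation(cfv: CashFlowVector, discount_rate: float) -> ValuationResult:
    """NPV at the given rate and IRR of the same (terminal-inclusive) vector."""
    root, multiple = irr(cfv)
    return ValuationResult(
        npv=npv(cfv, discount_rate),
        irr=root,
        discount_rate=discount_rate,
        terminal_value=cfv.terminal,
        irr_multiple_roots=multiple,
    )


def irr_batch(flows: np.ndarray, terminal: np.ndarray, n_bisect: int = 60) -> np.ndarray:
    """Vectorised IRR over a batch: ``flows`` (T, n), ``terminal`` (n,).

    Bisection between the bracket endpoints; NaN where NPV does not change
    sign over the bracket.  The scalar :func:`irr` is the reference
    implementation; this one trades the multi-root scan for speed (venture
    cash-flow patterns here have a single sign change in practice) and the
    two are cross-checked in the test-suite.
    """
    cf = flows.copy()
    cf[-1] += terminal
    T, n = cf.shape
    tt = np.arange(1, T + 1)[:, None]

    def f(r: np.ndarray) -> np.ndarray:
        return (cf / (1.0 + r)[None, :] ** tt).sum(axis=0)

    lo = np.full(n, IRR_BRACKET[0])
    hi = np.full(n, IRR_BRACKET[1])
    flo = f(lo)
    ok = np.sign(flo) != np.sign(f(hi))
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        left = np.sign(fm) == np.sign(flo)
        lo = np.where(left, mid, lo)
        flo = np.where(left, fm, flo)
        hi = np.where(left, hi, mid)
    out = 0.5 * (lo + hi)
    out[~ok] = np.nan
    return out
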