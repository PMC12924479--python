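"""Multi-rater ordinal agreement: Fleiss' kappa and rating summaries.

Ratings are items x raters on a fixed ordered category scale (default:
Non-existent < Poor < Good < Excellent).  Fleiss' kappa corrects the mean
observed pairwise agreement for the agreement expected by chance from the
category marginals:

    P_i   = (sum_j n_ij^2 - n) / (n (n - 1))      per-item agreement
    p_j   = sum_i n_ij / (N n)                    category marginal
    kappa = (mean_i P_i - sum_j p_j^2) / (1 - sum_j p_j^2)

Kappa is order-insensitive; the category order is kept only for reporting.
"""

from __future__ import annotations

import csv as _csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "DEFAULT_CATEGORIES",
    "RatingMatrix",
    "KappaResult",
    "fleiss_kappa",
    "rating_summary",
    "read_ratings_csv",
    "round_half_away",
]

DEFAULT_CATEGORIES = ("Non-existent", "Poor", "Good", "Excellent")


@dataclass(frozen=True)
class RatingMatrix:
    """Complete items x raters matrix of category indices (0-based)."""

    items: tuple[str, ...]
    raters: tuple[str, ...]
    categories: tuple[str, ...]
    codes: np.ndarray  # shape (N, n), integer category index per cell

    def __post_init__(self):
        codes = np.asarray(self.codes, dtype=int)
        object.__setattr__(self, "codes", codes)
        if codes.shape != (len(self.items), len(self.raters)):
            raise ValueError("codes shape must be (items, raters)")
        if len(self.categories) < 2:
            raise ValueError("at least two categories required")
        if codes.size and (codes.min() < 0 or codes.max() >= len(self.categories)):
            raise ValueError("category index out of range")

    @property
    def n_items(self) -> int:
        return len(self.items)

    @property
    def n_raters(self) -> int:
        return len(self.raters)

    def category_counts(self) -> np.ndarray:
        """n_ij: shape (N, k) counts of raters per item and category."""
        k = len(self.categories)
        return np.stack([np.bincount(row, minlength=k) for row in self.codes])


@dataclass(frozen=True)
class KappaResult:
    kappa: float | None  # None in the degenerate all-one-category case
    per_item_agreement: np.ndarray  # P_i, shape (N,)
    category_marginals: np.ndarray  # p_j, shape (k,)
    mean_agreement: float  # P-bar
    expected_agreement: float  # P-bar_e
    degenerate_perfect: bool = False

    def rounded(self, decimals: int = 2) -> float | None:
        return None if self.kappa is None else round_half_away(self.kappa, decimals)


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (Python's round() is banker's rounding)."""
    factor = 10.0 ** decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def fleiss_kappa(m: RatingMatrix) -> KappaResult:
    if m.n_raters < 2:
        raise ValueError("Fleiss' kappa needs at least two raters")
    if m.n_items < 1:
        raise ValueError("Fleiss' kappa needs at least one item")
    n = m.n_raters
    counts = m.category_counts()  # (N, k)
    p_i = (np.sum(counts**2, axis=1) - n) / (n * (n - 1))
    p_j = counts.sum(axis=0) / (m.n_items * n)
    p_bar = float(p_i.mean())
    p_e = float(np.sum(p_j**2))
    if p_e >= 1.0:
        # every rating in one category: observed agreement is perfect but the
        # chance-corrected statistic is 0/0
        return KappaResult(
            kappa=None,
            per_item_agreement=p_i,
            category_marginals=p_j,
            mean_agreement=p_bar,
            expected_agreement=p_e,
            degenerate_perfect=True,
        )
    kappa = (p_bar - p_e) / (1.0 - p_e)
    return KappaResult(
        kappa=float(kappa),
        per_item_agreement=p_i,
        category_marginals=p_j,
        mean_agreement=p_bar,
        expected_agreement=p_e,
    )


def rating_summary(m: RatingMatrix) -> list[dict]:
    """Per-item category counts, modal category (ties reported as such) and
    unanimity flag — the tabulation a consensus discussion starts from."""
    counts = m.category_counts()
    out = []
    for i, item in enumerate(m.items):
        row = counts[i]
        top = row.max()
        modes = [m.categories[j] for j in np.flatnonzero(row == top)]
        out.append(
            {
                "item": item,
                "counts": {cat: int(row[j]) for j, cat in enumerate(m.categories)},
                "mode": modes[0] if len(modes) == 1 else None,
                "tied_modes": modes if len(modes) > 1 else [],
                "unanimous": bool(top == m.n_raters),
            }
        )
    return out


def read_ratings_csv(path: str | Path, categories: tuple[str, ...] = DEFAULT_CATEGORIES) -> RatingMatrix:
    """Read a ratings file: header ``item,<rater>,...``; cells are category
    labels.  Ragged rows or unknown labels raise ValueError."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(_csv.reader(fh))
    if len(rows) < 2 or len(rows[0]) < 3:
        raise ValueError(f"{path}: need a header and at least one item with >= 2 raters")
    header = rows[0]
    raters = tuple(header[1:])
    cat_index = {c: i for i, c in enumerate(categories)}
    items, codes = [], []
    for lineno, row in enumerate(rows[1:], start=2):
        if len(row) != len(header):
            raise ValueError(f"{path}:{lineno}: ragged row")
        items.append(row[0])
        try:
            codes.append([cat_index[cell.strip()] for cell in row[1:]])
        except KeyError as exc:
            raise ValueError(f"{path}:{lineno}: unknown category {exc}") from exc
    return RatingMatrix(
        items=tuple(items), raters=raters, categories=tuple(categories),
        codes=np.asarray(codes, dtype=int),
    )
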