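"""Canonical model inputs and randomized generators for property testing.

The three data files in this directory encode the complete published inputs:
``table2.yaml`` (the 24 parameter triples plus run settings), ``ratings.csv``
(the six-factor system-fit ratings of the three evaluators), and
``criteria.yaml`` (the a-priori viability thresholds).  They live as files
rather than code constants so the CLI exercises the same I/O path users do.

The ``random_*`` generators produce valid-by-construction objects for
property tests: parameter sets with randomly ordered but consistent triples,
and rating matrices with uniform or unanimity-structured cells.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ..agreement import DEFAULT_CATEGORIES, RatingMatrix, read_ratings_csv
from ..parameters import (
    PARAMETER_SCHEMA,
    ParameterSet,
    ParameterSpec,
    RunSettings,
    load_parameter_set,
)
from ..sampling import RandomStream
from ..uncertainty import ViabilityCriteria

__all__ = [
    "fixture_path",
    "table2_fixture",
    "ratings_fixture",
    "criteria_fixture",
    "random_parameter_set",
    "random_rating_matrix",
]


def fixture_path(name: str) -> Path:
    """Filesystem path of a shipped fixture file."""
    return Path(resources.files(__package__) / name)


def table2_fixture() -> ParameterSet:
    """The canonical published parameter set (validated on load)."""
    return load_parameter_set(fixture_path("table2.yaml"))


def ratings_fixture() -> RatingMatrix:
    """The six-factor system-fit rating matrix (6 items x 3 raters)."""
    return read_ratings_csv(fixture_path("ratings.csv"))


def criteria_fixture() -> ViabilityCriteria:
    with fixture_path("criteria.yaml").open(encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    return ViabilityCriteria(**doc)


def random_parameter_set(
    stream: RandomStream,
    degenerate: bool = False,
    run: RunSettings | None = None,
) -> ParameterSet:
    """A random but valid parameter set over the full schema.

    Triples are built by sorting three draws around each spec's elicited
    range, so min <= median <= max always holds; ``degenerate`` collapses
    every triple to min == median == max.
    """
    base = table2_fixture()
    gen = stream.generator("random-parameter-set")
    specs = {}
    for name, spec in base.specs.items():
        unit, kind = PARAMETER_SCHEMA[name]
        lo_b = 0.0 if kind in ("proportion", "currency", "count") else spec.min * 0.5
        hi_b = 1.0 if kind == "proportion" else spec.max * 1.5
        draws = np.sort(gen.uniform(lo_b, hi_b, 3))
        if degenerate:
            draws[:] = draws[1]
        specs[name] = ParameterSpec(
            name=name, min=float(draws[0]), median=float(draws[1]),
            max=float(draws[2]), unit=unit, kind=kind,
        )
    return ParameterSet(specs=specs, run=run or base.run)


def random_rating_matrix(
    stream: RandomStream,
    n_items: int = 6,
    n_raters: int = 3,
    n_categories: int = 4,
    unanimous: bool = False,
) -> RatingMatrix:
    """Uniform random ratings; ``unanimous`` gives one category per item
    (a kappa = 1 configuration whenever >= 2 categories are used)."""
    if n_items < 1 or n_raters < 1 or n_categories < 2:
        raise ValueError("need n_items, n_raters >= 1 and n_categories >= 2")
    gen = stream.generator("random-rating-matrix")
    if unanimous:
        per_item = gen.integers(0, n_categories, size=n_items)
        codes = np.repeat(per_item[:, None], n_raters, axis=1)
    else:
        codes = gen.integers(0, n_categories, size=(n_items, n_raters))
    categories = tuple(
        DEFAULT_CATEGORIES[j] if j < len(DEFAULT_CATEGORIES) else f"cat{j}"
        for j in range(n_categories)
    )
    return RatingMatrix(
        items=tuple(f"item{i}" for i in range(n_items)),
        raters=tuple(f"rater{r}" for r in range(n_raters)),
        categories=categories,
        codes=codes,
    )
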