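"""Random draws from the parameter space.

Each parameter is sampled from an independent triangular distribution with
lower = min, mode = median, upper = max — the minimal-assumption family for a
(median, min, max) elicitation.  Uniform(min, max) and PERT alternates sit
behind the same interface.

Reproducibility contract: every (seed, stream label, parameter name) triple
maps to its own deterministic substream.  Because substreams are keyed by
parameter name, fixing one parameter (an override) leaves every other
parameter's draws bit-identical — the common-random-numbers property that the
sensitivity grids rely on.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field

import numpy as np

from .parameters import ParameterSet, ParameterSpec, ScenarioParameters

__all__ = ["RandomStream", "sample_scenario", "sample_batch", "scenario_pair_with_override"]

log = logging.getLogger(__name__)

DISTRIBUTIONS = ("triangular", "uniform", "pert")


def _label_hash(text: str) -> int:
    # stable across processes (unlike hash()); kept below 2**31
    return zlib.crc32(text.encode("utf-8")) & 0x7FFFFFFF


@dataclass
class RandomStream:
    """A named, seeded family of per-parameter generators."""

    seed: int
    label: str = "default"
    _gens: dict = field(default_factory=dict, repr=False)

    def generator(self, name: str) -> np.random.Generator:
        if name not in self._gens:
            ss = np.random.SeedSequence(
                [int(self.seed) & 0x7FFFFFFF, _label_hash(self.label), _label_hash(name)]
            )
            self._gens[name] = np.random.default_rng(ss)
        return self._gens[name]


def draw_values(
    spec: ParameterSpec,
    gen: np.random.Generator,
    size: int,
    distribution: str = "triangular",
) -> np.ndarray:
    """``size`` independent draws for one parameter.

    A degenerate spec (min == max) yields the constant without consuming
    random state, so adding a constant parameter never perturbs the others.
    """
    if spec.is_degenerate:
        return np.full(size, spec.median, dtype=float)
    if distribution == "triangular":
        return gen.triangular(spec.min, spec.median, spec.max, size)
    if distribution == "uniform":
        return gen.uniform(spec.min, spec.max, size)
    if distribution == "pert":
        # modified-PERT via its Beta reparameterisation, shape lambda = 4
        lam = 4.0
        a, m, b = spec.min, spec.median, spec.max
        alpha = 1.0 + lam * (m - a) / (b - a)
        beta = 1.0 + lam * (b - m) / (b - a)
        return a + (b - a) * gen.beta(alpha, beta, size)
    raise ValueError(f"unknown distribution '{distribution}'")


def sample_batch(
    pset: ParameterSet,
    stream: RandomStream,
    n: int,
    overrides: dict[str, float] | None = None,
    distribution: str = "triangular",
) -> dict[str, np.ndarray]:
    """Draw ``n`` scenarios at once: name -> array of length n.

    Overridden parameters are pinned to the given value; because substreams
    are per-parameter, the non-overridden columns are identical across calls
    with the same stream regardless of the override set.  Override values
    outside [min, max] are accepted with a warning — sensitivity grids may
    deliberately probe beyond the elicited range.
    """
    overrides = overrides or {}
    unknown = set(overrides) - set(pset.specs)
    if unknown:
        raise KeyError(f"unknown override name(s): {sorted(unknown)}")
    out: dict[str, np.ndarray] = {}
    for name, spec in pset.specs.items():
        if name in overrides:
            value = float(overrides[name])
            if not spec.contains(value):
                log.warning(
                    "override %s=%s outside elicited range [%s, %s]",
                    name, value, spec.min, spec.max,
                )
            out[name] = np.full(n, value, dtype=float)
        else:
            out[name] = draw_values(spec, stream.generator(name), n, distribution)
    return out


def sample_scenario(
    pset: ParameterSet,
    stream: RandomStream,
    distribution: str = "triangular",
) -> ScenarioParameters:
    """One random scenario.  Successive calls advance the stream."""
    batch = sample_batch(pset, stream, 1, distribution=distribution)
    return ScenarioParameters(
        values={k: float(v[0]) for k, v in batch.items()}, run=pset.run
    )


def scenario_pair_with_override(
    pset: ParameterSet,
    stream: RandomStream,
    overrides: dict[str, float],
    distribution: str = "triangular",
) -> ScenarioParameters:
    """One scenario with some parameters pinned (common random numbers).

    The same stream state yields identical non-overridden draws whatever the
    override values are, so paired comparisons across override settings see
    the same background uncertainty.
    """
    batch = sample_batch(pset, stream, 1, overrides=overrides, distribution=distribution)
    return ScenarioParameters(
        values={k: float(v[0]) for k, v in batch.items()}, run=pset.run
    )
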