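"""Parameter space and run configuration for the venture model.

The model is driven by 24 parameters, each specified as a (median, min, max)
triple in its natural unit.  Proportions printed as percentages elsewhere are
stored here as fractions in [0, 1] — a deliberate normalisation that removes a
silent x100 failure mode.  Run-level settings (horizon, Monte Carlo iteration
count, terminal earnings multiple, adoption-ramp schedule, seed) live next to
the parameters so that a single config file fully determines a run.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "ParameterSpec",
    "RunSettings",
    "ParameterSet",
    "ScenarioParameters",
    "ParameterValidationError",
    "PARAMETER_SCHEMA",
    "PARAMETER_NAMES",
    "load_parameter_set",
    "write_parameter_set",
    "median_scenario",
]


class ParameterValidationError(ValueError):
    """Raised when a parameter file or object violates the schema."""


#: Canonical catalogue of model symbols: name -> (unit, kind).
#: ``kind`` drives validation: proportions must lie in [0, 1]; currency and
#: count parameters must be non-negative.
PARAMETER_SCHEMA: dict[str, tuple[str, str]] = {
    "adult_population": ("persons", "count"),
    "screening_eligibility": ("proportion", "proportion"),
    "ifg_prevalence": ("proportion", "proportion"),
    "undiagnosed_fraction": ("proportion", "proportion"),
    "screening_participation": ("proportion", "proportion"),
    "adoption_rate": ("proportion", "proportion"),
    "paid_conversion": ("proportion", "proportion"),
    "churn_rate": ("proportion", "proportion"),
    "customer_lifetime_years": ("years", "rate"),
    "cac": ("CHF", "currency"),
    "price_monthly": ("CHF/month", "currency"),
    "technician_per_user_ratio": ("users/FTE", "ratio"),
    "manager_per_technician_ratio": ("FTE/FTE", "ratio"),
    "technician_salary": ("CHF/year", "currency"),
    "manager_salary": ("CHF/year", "currency"),
    "office_supplies_per_worker": ("CHF/year", "currency"),
    "office_rent_per_worker": ("CHF/year", "currency"),
    "call_center_per_user": ("CHF/year", "currency"),
    "backend_per_user": ("CHF/year", "currency"),
    "app_development": ("CHF", "currency"),
    "app_maintenance": ("CHF/year", "currency"),
    "ce_mdr_certification": ("CHF", "currency"),
    "revfadp_compliance": ("CHF/year", "currency"),
    "discount_rate": ("proportion", "proportion"),
}

PARAMETER_NAMES: tuple[str, ...] = tuple(PARAMETER_SCHEMA)


@dataclass(frozen=True)
class ParameterSpec:
    """One model symbol with its uncertainty triple.

    ``median`` is the mode of the triangular sampling distribution; ``min``
    and ``max`` are its support.  A degenerate triple (min == median == max)
    denotes a documented constant.
    """

    name: str
    median: float
    min: float
    max: float
    unit: str = ""
    kind: str = "rate"

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max):
            raise ParameterValidationError(
                f"parameter '{self.name}': ordering min <= median <= max violated "
                f"({self.min}, {self.median}, {self.max})"
            )
        if self.kind == "proportion" and not (0.0 <= self.min and self.max <= 1.0):
            raise ParameterValidationError(
                f"parameter '{self.name}': proportion outside [0, 1] "
                f"({self.min}..{self.max}); store percentages as fractions"
            )
        if self.kind in ("currency", "count") and self.min < 0:
            raise ParameterValidationError(
                f"parameter '{self.name}': {self.kind} must be non-negative"
            )

    @property
    def is_degenerate(self) -> bool:
        return self.min == self.max

    def contains(self, value: float) -> bool:
        return self.min <= value <= self.max


@dataclass(frozen=True)
class RunSettings:
    """Run-level knobs shared by every computation.

    adoption_ramp_shape/strength define the multiplier applied to the Year-1
    acquisition flow: ``log`` gives 1 + strength*ln(t) (default, calibrated
    against the published Year-1/4/7 user anchors); ``linear`` gives
    1 + strength*(t-1); ``none`` holds acquisition flat.
    ``breakeven_includes_terminal`` controls whether the Monte Carlo breakeven
    check adds the terminal (exit) value to the horizon-year cumulative
    position; the operating ledger itself never includes it.
    """

    horizon_years: int = 7
    n_iterations: int = 5000
    terminal_multiple: float = 10.0
    seed: int = 20260128
    acquisition_cadence_factor: float = 12.0
    adoption_ramp_shape: str = "log"
    adoption_ramp_strength: float = 0.85
    breakeven_includes_terminal: bool = True
    upfront_cost_year: int = 1

    def __post_init__(self) -> None:
        if self.horizon_years < 1:
            raise ParameterValidationError("horizon_years must be >= 1")
        if self.n_iterations < 1:
            raise ParameterValidationError("n_iterations must be >= 1")
        if self.terminal_multiple < 0:
            raise ParameterValidationError("terminal_multiple must be >= 0")
        if self.adoption_ramp_shape not in ("log", "linear", "none"):
            raise ParameterValidationError(
                f"unknown adoption_ramp_shape '{self.adoption_ramp_shape}'"
            )
        if self.upfront_cost_year not in (0, 1):
            raise ParameterValidationError("upfront_cost_year must be 0 or 1")


@dataclass(frozen=True)
class ParameterSet:
    """The validated parameter space: exactly one spec per model symbol."""

    specs: Mapping[str, ParameterSpec]
    run: RunSettings = field(default_factory=RunSettings)

    def __post_init__(self) -> None:
        unknown = set(self.specs) - set(PARAMETER_SCHEMA)
        if unknown:
            raise ParameterValidationError(
                f"unknown parameter name(s): {sorted(unknown)}"
            )
        missing = set(PARAMETER_SCHEMA) - set(self.specs)
        if missing:
            raise ParameterValidationError(
                f"missing parameter(s): {sorted(missing)}"
            )

    def __getitem__(self, name: str) -> ParameterSpec:
        return self.specs[name]

    def with_spec(self, spec: ParameterSpec) -> "ParameterSet":
        """Return a copy with one spec replaced (name must already exist)."""
        if spec.name not in self.specs:
            raise ParameterValidationError(f"unknown parameter '{spec.name}'")
        specs = dict(self.specs)
        specs[spec.name] = spec
        return ParameterSet(specs=specs, run=self.run)

    def with_run(self, **changes) -> "ParameterSet":
        return ParameterSet(specs=self.specs, run=replace(self.run, **changes))


@dataclass(frozen=True)
class ScenarioParameters:
    """One concrete point of the parameter space plus the run settings."""

    values: Mapping[str, float]
    run: RunSettings = field(default_factory=RunSettings)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def validate_against(self, pset: ParameterSet) -> None:
        for name, value in self.values.items():
            spec = pset[name]
            if not spec.contains(value):
                raise ParameterValidationError(
                    f"parameter '{name}': value {value} outside "
                    f"[{spec.min}, {spec.max}]"
                )


def median_scenario(pset: ParameterSet) -> ScenarioParameters:
    """The deterministic base case: every parameter at its median."""
    return ScenarioParameters(
        values={name: spec.median for name, spec in pset.specs.items()},
        run=pset.run,
    )


def _coerce_spec(name: str, raw) -> ParameterSpec:
    unit, kind = PARAMETER_SCHEMA[name]
    if isinstance(raw, Mapping):
        try:
            median, lo, hi = float(raw["median"]), float(raw["min"]), float(raw["max"])
        except KeyError as exc:
            raise ParameterValidationError(
                f"parameter '{name}': missing field {exc}"
            ) from exc
        file_unit = raw.get("unit")
        if file_unit is not None and file_unit != unit:
            raise ParameterValidationError(
                f"parameter '{name}': unit '{file_unit}' does not match "
                f"schema unit '{unit}'"
            )
    else:  # bare number: a documented constant
        median = lo = hi = float(raw)
    return ParameterSpec(name=name, median=median, min=lo, max=hi, unit=unit, kind=kind)


def load_parameter_set(config_path: str | Path) -> ParameterSet:
    """Read a YAML (or JSON — YAML is a superset) config into a ParameterSet.

    The file holds two top-level maps: ``parameters`` (name ->
    {median, min, max, unit}) and ``run`` (run-level settings, all optional).
    Every schema symbol must be present; unknown keys are rejected with the
    offending name in the message.
    """
    path = Path(config_path)
    with path.open("r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping) or "parameters" not in doc:
        raise ParameterValidationError(
            f"{path}: expected top-level 'parameters' map"
        )
    raw_params = doc["parameters"]
    unknown = set(raw_params) - set(PARAMETER_SCHEMA)
    if unknown:
        raise ParameterValidationError(f"unknown parameter name(s): {sorted(unknown)}")
    specs = {name: _coerce_spec(name, raw) for name, raw in raw_params.items()}

    raw_run = doc.get("run", {}) or {}
    valid_run_fields = {f.name for f in fields(RunSettings)}
    unknown_run = set(raw_run) - valid_run_fields
    if unknown_run:
        raise ParameterValidationError(f"unknown run key(s): {sorted(unknown_run)}")
    return ParameterSet(specs=specs, run=RunSettings(**raw_run))


def write_parameter_set(pset: ParameterSet, path: str | Path) -> Path:
    """Persist a ParameterSet so that :func:`load_parameter_set` reads it back
    equal.  Run-level defaults are written explicitly."""
    path = Path(path)
    doc = {
        "parameters": {
            name: {
                "median": _plain(spec.median),
                "min": _plain(spec.min),
                "max": _plain(spec.max),
                "unit": spec.unit,
            }
            for name, spec in pset.specs.items()
        },
        "run": {f.name: getattr(pset.run, f.name) for f in fields(RunSettings)},
    }
    with path.open("w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
    return path


def _plain(x: float):
    # write integral floats as ints for readable diffs
    if isinstance(x, float) and math.isfinite(x) and x == int(x) and abs(x) < 1e15:
        return int(x)
    return x
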