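"""Model inputs: parameter inventory, validation, and the packaged base case.

Every input of the cohort model lives here: the four Weibull curves
(PFS/OS for each arm), the cost/utility/incidence parameters with their
one-way ranges and probabilistic-sampling families, and global model
settings (cycle length, discounting, willingness-to-pay, treatment caps).

The packaged fixture ``"builtin"`` holds the base case for first-line
sintilimab plus chemotherapy (SIDCHM) versus placebo plus chemotherapy
(PLCHM) in advanced or metastatic oesophageal squamous cell carcinoma,
costed in 2021 USD from the Chinese healthcare-system perspective.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

__all__ = [
    "WeibullParams",
    "ModelParameter",
    "ModelSettings",
    "ParameterSet",
    "ParameterValidationError",
    "load_parameters",
    "clamp_ranges",
    "AE_NAMES",
    "ARMS",
    "CURVE_KEYS",
]

ARMS = ("sidchm", "plchm")
AE_NAMES = (
    "anemia",
    "leukopenia",
    "nausea_vomiting",
    "neutropenia",
    "asthenia_decreased_appetite",
    "thrombocytopenia",
    "febrile_neutropenia",
)
CURVE_KEYS = ("sidchm_pfs", "sidchm_os", "plchm_pfs", "plchm_os")
DISTRIBUTIONS = ("beta", "gamma", "normal", "fixed")

#: parameters that are probabilities or utilities and must live in [0, 1]
_PROB_PREFIXES = ("ae_inc_", "utility_", "prop_")


class ParameterValidationError(ValueError):
    """Raised when a parameter file fails validation.

    Carries the full list of problems in ``errors`` so that a bad config is
    reported in one pass rather than one failure at a time.
    """

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("parameter validation failed:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class WeibullParams:
    """Weibull survival curve S(t) = exp(-scale * t**shape), t in cycles."""

    scale: float
    shape: float

    def __post_init__(self):
        if not (self.scale > 0 and math.isfinite(self.scale)):
            raise ValueError(f"Weibull scale must be positive, got {self.scale}")
        if not (self.shape > 0 and math.isfinite(self.shape)):
            raise ValueError(f"Weibull shape must be positive, got {self.shape}")


@dataclass(frozen=True)
class ModelParameter:
    """A scalar model input with its one-way range and sampling family.

    ``value`` is the working value used by the engine; it starts at ``base``
    and is replaced (never mutated) by the sensitivity analyses.
    """

    name: str
    base: float
    low: float
    high: float
    dist: str
    units: str = ""
    value: float = None  # type: ignore[assignment]

    def __post_init__(self):
        if self.value is None:
            object.__setattr__(self, "value", self.base)

    @property
    def is_probability(self) -> bool:
        return self.name.startswith(_PROB_PREFIXES)

    def with_value(self, value: float) -> "ModelParameter":
        return replace(self, value=float(value))


@dataclass(frozen=True)
class ModelSettings:
    """Global model conventions shared by both arms."""

    cycle_days: float = 21.0
    wtp: float = 37653.0
    death_horizon_threshold: float = 0.99
    max_cycles: int = 160
    sintilimab_max_cycles: int = 35
    chemo_max_cycles: int = 6
    half_cycle_correction: bool = False
    background_mortality_annual: float = 0.007
    vial_rounding: bool = False
    tests_in_pd: bool = True
    followup_in_pd: bool = True

    def __post_init__(self):
        if self.cycle_days <= 0:
            raise ValueError("cycle_days must be positive")
        if not (0 < self.death_horizon_threshold <= 1):
            raise ValueError("death_horizon_threshold must lie in (0, 1]")
        if not (0 <= self.background_mortality_annual < 1):
            raise ValueError("background mortality must be a probability")

    @property
    def cycle_years(self) -> float:
        return self.cycle_days / 365.0


@dataclass
class ParameterSet:
    """The complete, validated input vector of the model."""

    params: dict[str, ModelParameter]
    weibull: dict[str, WeibullParams]
    settings: ModelSettings
    clamp_report: list[str] = field(default_factory=list)

    def __getitem__(self, name: str) -> ModelParameter:
        return self.params[name]

    def value(self, name: str) -> float:
        return self.params[name].value

    @property
    def discount_annual(self) -> float:
        return self.value("discount_rate")

    def with_values(self, updates: Mapping[str, float]) -> "ParameterSet":
        """Copy with the named parameters set to new working values."""
        new = dict(self.params)
        for name, v in updates.items():
            if name not in new:
                raise KeyError(f"unknown parameter {name!r}")
            new[name] = new[name].with_value(v)
        return ParameterSet(new, dict(self.weibull), self.settings, list(self.clamp_report))

    def with_curves(self, curves: Mapping[str, WeibullParams]) -> "ParameterSet":
        """Copy with some survival curves replaced (used for subgroups)."""
        wb = dict(self.weibull)
        for key, wp in curves.items():
            if key not in CURVE_KEYS:
                raise KeyError(f"unknown survival curve {key!r}")
            wb[key] = wp
        return ParameterSet(dict(self.params), wb, self.settings, list(self.clamp_report))

    def ae_incidences(self, arm: str) -> dict[str, float]:
        return {ae: self.value(f"ae_inc_{arm}_{ae}") for ae in AE_NAMES}

    def ae_costs(self) -> dict[str, float]:
        return {ae: self.value(f"ae_cost_{ae}") for ae in AE_NAMES}

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "settings": {
                k: getattr(self.settings, k)
                for k in (
                    "cycle_days", "wtp", "death_horizon_threshold", "max_cycles",
                    "sintilimab_max_cycles", "chemo_max_cycles", "half_cycle_correction",
                    "background_mortality_annual", "vial_rounding", "tests_in_pd",
                    "followup_in_pd",
                )
            },
            "survival": {
                k: {"scale": wp.scale, "shape": wp.shape} for k, wp in self.weibull.items()
            },
            "parameters": {
                p.name: {"base": p.base, "low": p.low, "high": p.high,
                         "dist": p.dist, "units": p.units}
                for p in self.params.values()
            },
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


def _builtin_text() -> str:
    return resources.files("escc_cea").joinpath("data/sintilimab_escc.yaml").read_text()


def load_parameters(config_path: str | Path = "builtin") -> ParameterSet:
    """Load and validate a parameter file (YAML or JSON; JSON is a YAML subset).

    ``"builtin"`` selects the packaged base case. Validation failures are
    collected and raised together as :class:`ParameterValidationError`;
    nothing is silently repaired except the documented range clamping, which
    is applied by :func:`clamp_ranges` and logged in ``clamp_report``.
    """
    if str(config_path) == "builtin":
        raw = yaml.safe_load(_builtin_text())
    else:
        raw = yaml.safe_load(Path(config_path).read_text())

    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ParameterValidationError(["config root must be a mapping"])

    try:
        settings = ModelSettings(**raw.get("settings", {}))
    except (TypeError, ValueError) as e:
        errors.append(f"settings: {e}")
        settings = ModelSettings()

    weibull: dict[str, WeibullParams] = {}
    surv = raw.get("survival", {})
    for key in CURVE_KEYS:
        if key not in surv:
            errors.append(f"missing survival curve {key!r}")
            continue
        try:
            weibull[key] = WeibullParams(**surv[key])
        except (TypeError, ValueError) as e:
            errors.append(f"survival curve {key!r}: {e}")

    params: dict[str, ModelParameter] = {}
    expected = _expected_inventory()
    given = raw.get("parameters", {})
    for name in expected:
        if name not in given:
            errors.append(f"missing parameter {name!r}")
    for name, spec in given.items():
        if name not in expected:
            errors.append(f"unexpected parameter {name!r}")
            continue
        try:
            p = ModelParameter(name=name, **spec)
        except TypeError as e:
            errors.append(f"parameter {name!r}: {e}")
            continue
        if p.dist not in DISTRIBUTIONS:
            errors.append(f"parameter {name!r}: unknown distribution {p.dist!r}")
        if p.base < 0 and not name.startswith("discount"):
            errors.append(f"parameter {name!r}: negative base value {p.base}")
        if p.is_probability and not (0 <= p.base <= 1):
            errors.append(f"parameter {name!r}: probability/utility base {p.base} outside [0, 1]")
        params[name] = p

    if errors:
        raise ParameterValidationError(errors)

    ps = ParameterSet(params, weibull, settings)
    ps = clamp_ranges(ps)

    post = []
    for p in ps.params.values():
        if not (p.low <= p.base <= p.high):
            post.append(f"parameter {p.name!r}: base {p.base} outside [{p.low}, {p.high}]")
    s = ps.value("prop_paclitaxel") + ps.value("prop_fluorouracil")
    if abs(s - 1.0) > 1e-9:
        post.append(f"regimen proportions sum to {s}, expected 1")
    if post:
        raise ParameterValidationError(post)
    return ps


def clamp_ranges(ps: ParameterSet) -> ParameterSet:
    """Clamp probability-like one-way ranges into [0, 1], logging each change.

    The published table prints an upper bound of 1.12 for the paclitaxel
    regimen proportion; a proportion cannot exceed 1, so bounds are capped
    and the adjustment recorded in ``clamp_report``.
    """
    new = dict(ps.params)
    report = list(ps.clamp_report)
    for name, p in ps.params.items():
        if not p.is_probability:
            continue
        lo, hi = p.low, p.high
        lo2, hi2 = max(lo, 0.0), min(hi, 1.0)
        if (lo2, hi2) != (lo, hi):
            new[name] = replace(p, low=lo2, high=hi2)
            report.append(f"{name}: range [{lo}, {hi}] clamped to [{lo2}, {hi2}]")
    return ParameterSet(new, dict(ps.weibull), ps.settings, report)


def _expected_inventory() -> list[str]:
    names = [f"ae_inc_{arm}_{ae}" for arm in ARMS for ae in AE_NAMES]
    names += [f"ae_cost_{ae}" for ae in AE_NAMES]
    names += [f"price_{d}" for d in ("paclitaxel", "cisplatin", "fluorouracil", "sintilimab")]
    names += ["cost_followup_per_cycle", "cost_tests", "cost_end_of_life", "cost_bsc"]
    names += ["utility_pfs", "utility_pd"]
    names += ["prop_paclitaxel", "prop_fluorouracil"]
    names += ["bsa", "discount_rate"]
    return names
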