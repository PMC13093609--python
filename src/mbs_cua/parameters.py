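"""Model parameters: point values, uncertainty distributions, sensitivity ranges.

Every input of the cost-utility model lives here: the cohort profile
(initial age and BMI-class mix), the annual transition probabilities for
both strategies, per-state utility weights with age and diabetes
decrements, per-state management costs with class-cost differentials,
first-year surgery costs, diabetes management costs, discounting and the
willingness-to-pay threshold.  ``load_parameters`` reads a YAML/JSON-style
mapping (or the packaged defaults) into a validated :class:`ParameterSet`.

Several modelling conventions the source material leaves open are exposed
as :class:`ModelOptions` flags rather than hard-coded; the defaults are
documented in docs/methods.md.
"""

from __future__ import annotations

import copy
import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import yaml

from .distributions import DistributionSpec
from .lifetable import DEFAULT_ANCHORS, LifeTable, build_lifetable
from .states import ALIVE_STATES, HealthState

__all__ = [
    "ModelOptions",
    "ParameterSet",
    "ConfigurationError",
    "ValidationError",
    "load_parameters",
    "default_parameters",
    "default_lifetable",
    "PSA_PARAMETERS",
]


class ConfigurationError(KeyError):
    """A required configuration key is missing."""


class ValidationError(ValueError):
    """A parameter violates one of its invariants."""


_ATOL = 1e-9


@dataclass(frozen=True)
class ModelOptions:
    """Conventions the published description leaves open.

    class_inflator_mode:
        "differential" (default) treats the 5%/10% OB2/OB3 cost inflators
        as one-time class-cost multipliers relative to the pooled OB2/OB3
        cost; "compound" compounds them annually, c·(1+g)^cycle.
    compound_diabetes_cost:
        diabetes costs grow 5% per year of diabetes when True (default).
    year1_timing:
        "entry" (default) applies the 12-month post-surgery transition at
        model entry so cycle-0 occupancy and utilities already reflect
        surgery; "first-cycle" applies it as the first annual transition.
    surgery_cost_replaces_management:
        first-year surgery cost replaces (True, default) or adds to the
        state management cost in cycle 0.
    half_cycle_correction:
        half-weight the first cycle and add a half terminal cycle.
    horizon_mode:
        "cycles" (default) runs ``horizon_cycles`` annual cycles;
        "to-age-90" runs round(90 - initial_age) cycles.
    sw_below_wtp:
        "always" (default) counts the lower-left CE-plane quadrant
        (cheaper, less effective) as below the WTP threshold, matching the
        published composite proportion; "nmb" requires positive net
        monetary benefit there.
    monotone_utilities:
        reject PSA utility draws violating u(OW) >= u(OB1) >= u(OB2)
        >= u(OB3) (off by default; marginals only are published).
    """

    class_inflator_mode: str = "differential"
    compound_diabetes_cost: bool = True
    year1_timing: str = "entry"
    surgery_cost_replaces_management: bool = True
    half_cycle_correction: bool = False
    horizon_mode: str = "cycles"
    sw_below_wtp: str = "always"
    monotone_utilities: bool = False

    def __post_init__(self) -> None:
        if self.class_inflator_mode not in ("differential", "compound"):
            raise ValidationError(
                "class_inflator_mode must be 'differential' or 'compound'"
            )
        if self.year1_timing not in ("entry", "first-cycle"):
            raise ValidationError("year1_timing must be 'entry' or 'first-cycle'")
        if self.horizon_mode not in ("cycles", "to-age-90"):
            raise ValidationError("horizon_mode must be 'cycles' or 'to-age-90'")
        if self.sw_below_wtp not in ("always", "nmb"):
            raise ValidationError("sw_below_wtp must be 'always' or 'nmb'")


# Table-of-record point values. Keys mirror the config schema.
_DEFAULTS: dict = {
    "initial_age": 52.4,
    "horizon_cycles": 40,
    "discount_rate": 0.05,
    "wtp": 64000.0,
    "initial_distribution": {"OW": 0.0, "OB1": 0.005, "OB2": 0.200, "OB3": 0.795},
    "rr_diabetes_mortality": 1.54,
    "surgical_mortality": 0.005,
    "diabetes_fraction_surgery": 0.101,
    "diabetes_fraction_uc": 1.0,
    "year1_surgery_transitions": {
        "OB1": {"OW": 1.00, "OB1": 0.00},
        "OB2": {"OW": 0.64, "OB1": 0.31, "OB2": 0.05},
        "OB3": {"OW": 0.34, "OB1": 0.23, "OB2": 0.19, "OB3": 0.24},
    },
    "up_surgery": 0.018,
    "down_surgery": 0.0,
    "up_uc": 0.0603,
    "down_uc": 0.0557,
    "utilities": {"OW": 0.782, "OB1": 0.730, "OB2": 0.599, "OB3": 0.550},
    "disutility_age": 0.003,
    "disutility_diabetes": 0.116,
    "surgery_cost": {"OB1": 15734.0, "OB2": 15734.0, "OB3": 18242.0},
    "management_cost": {"OW": 6762.0, "OB1": 7574.0, "OB2": 8926.0, "OB3": 8926.0},
    "inflator_ob2": 0.05,
    "inflator_ob3": 0.10,
    "diabetes_cost": 3997.0,
    "diabetes_cost_growth": 0.05,
}

# PSA sampling distributions (mean/sd as printed). Order of PSA_PARAMETERS
# is the canonical sub-stream order: append new parameters at the end so
# existing draws are not perturbed.
_DISTRIBUTIONS: dict[str, DistributionSpec] = {
    "initial_age": DistributionSpec("triangular", 52.4, min=28.1, mode=52.4, max=65.0),
    "surgical_mortality": DistributionSpec("beta", 0.005, 0.01),
    "up_surgery": DistributionSpec("beta", 0.018, 0.006),
    "up_uc": DistributionSpec("beta", 0.0603, 0.0047),
    "down_uc": DistributionSpec("beta", 0.0557, 0.0047),
    "utility_ow": DistributionSpec("beta", 0.782, 0.212),
    "utility_ob1": DistributionSpec("beta", 0.730, 0.229),
    "utility_ob2": DistributionSpec("beta", 0.599, 0.252),
    "utility_ob3": DistributionSpec("beta", 0.550, 0.275),
    "disutility_diabetes": DistributionSpec("beta", 0.116, 0.034),
    "disutility_age": DistributionSpec("beta", 0.003, 0.002),
    "surgery_cost_ob1_ob2": DistributionSpec("gamma", 15734.0, 12886.0),
    "surgery_cost_ob3": DistributionSpec("gamma", 18242.0, 21165.0),
    "management_cost_ow": DistributionSpec("gamma", 6762.0, 15568.0),
    "management_cost_ob1": DistributionSpec("gamma", 7574.0, 16008.0),
    "management_cost_ob2_ob3": DistributionSpec("gamma", 8926.0, 18599.0),
    "diabetes_cost": DistributionSpec("gamma", 3997.0, 248.0),
}

PSA_PARAMETERS = tuple(_DISTRIBUTIONS)

# One-way sensitivity ranges printed alongside the point values.
_SA_RANGES: dict[str, tuple[float, float]] = {
    "initial_age": (28.0, 65.0),
    "discount_rate": (0.03, 0.07),
    "horizon_cycles": (25, 55),
    "rr_diabetes_mortality": (1.33, 1.78),
    "diabetes_fraction_surgery": (0.05, 0.15),
    "inflator_ob2": (0.0, 0.10),
    "inflator_ob3": (0.0, 0.20),
}

_STATE_KEYS = ("OW", "OB1", "OB2", "OB3")


def _as_state_vector(mapping: Mapping[str, float], name: str) -> np.ndarray:
    try:
        vec = np.array([float(mapping[k]) for k in _STATE_KEYS])
    except KeyError as exc:
        raise ConfigurationError(f"{name} is missing state {exc.args[0]!r}") from exc
    return vec


@dataclass(frozen=True)
class ParameterSet:
    """Validated inputs for one model run (both strategies)."""

    initial_age: float
    horizon_cycles: int
    discount_rate: float
    wtp: float
    initial_distribution: np.ndarray  # length 4, over alive states
    rr_diabetes_mortality: float
    surgical_mortality: float
    diabetes_fraction_surgery: float
    diabetes_fraction_uc: float
    year1_surgery_transitions: dict
    up_surgery: float
    down_surgery: float
    up_uc: float
    down_uc: float
    utilities: np.ndarray  # length 4
    disutility_age: float
    disutility_diabetes: float
    surgery_cost: dict
    management_cost: np.ndarray  # length 4
    inflator_ob2: float
    inflator_ob3: float
    diabetes_cost: float
    diabetes_cost_growth: float
    distributions: dict = field(default_factory=dict)
    sa_ranges: dict = field(default_factory=dict)
    options: ModelOptions = field(default_factory=ModelOptions)

    # -- validation ---------------------------------------------------
    def __post_init__(self) -> None:
        object.__setattr__(
            self, "initial_distribution",
            np.asarray(self.initial_distribution, dtype=float),
        )
        object.__setattr__(self, "utilities", np.asarray(self.utilities, dtype=float))
        object.__setattr__(
            self, "management_cost", np.asarray(self.management_cost, dtype=float)
        )
        self._validate()

    def _validate(self) -> None:
        def _prob(name: str, value: float) -> None:
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {value}")

        if self.horizon_cycles < 1:
            raise ValidationError("horizon_cycles must be >= 1")
        if self.discount_rate < 0.0:
            raise ValidationError("discount_rate must be >= 0")
        if self.wtp < 0.0:
            raise ValidationError("wtp must be >= 0")
        if self.initial_distribution.shape != (4,):
            raise ValidationError("initial_distribution must cover the 4 alive states")
        if np.any(self.initial_distribution < 0):
            raise ValidationError("initial_distribution entries must be >= 0")
        total = float(self.initial_distribution.sum())
        if abs(total - 1.0) > _ATOL:
            raise ValidationError(
                f"initial_distribution must sum to 1 (got {total:.6g})"
            )
        for name in (
            "surgical_mortality",
            "diabetes_fraction_surgery",
            "diabetes_fraction_uc",
            "up_surgery",
            "down_surgery",
            "up_uc",
            "down_uc",
        ):
            _prob(name, getattr(self, name))
        if self.up_surgery + self.down_surgery > 1.0 + _ATOL:
            raise ValidationError("up_surgery + down_surgery must be <= 1")
        if self.up_uc + self.down_uc > 1.0 + _ATOL:
            raise ValidationError("up_uc + down_uc must be <= 1")
        if self.rr_diabetes_mortality < 0:
            raise ValidationError("rr_diabetes_mortality must be >= 0")
        if np.any((self.utilities < 0) | (self.utilities > 1)):
            raise ValidationError("utilities must lie in [0, 1]")
        if np.any(self.management_cost < 0):
            raise ValidationError("management_cost values must be >= 0")
        for k, v in self.surgery_cost.items():
            if v < 0:
                raise ValidationError(f"surgery_cost[{k}] must be >= 0")
        if self.diabetes_cost < 0:
            raise ValidationError("diabetes_cost must be >= 0")
        for origin, row in self.year1_surgery_transitions.items():
            total = sum(row.values())
            if abs(total - 1.0) > _ATOL:
                raise ValidationError(
                    f"year1_surgery_transitions[{origin}] must sum to 1 "
                    f"(got {total:.6g})"
                )
            for dest, p in row.items():
                _prob(f"year1_surgery_transitions[{origin}][{dest}]", p)

    # -- accessors ----------------------------------------------------
    @property
    def initial_occupancy(self) -> np.ndarray:
        """Length-5 occupancy vector (alive states + DEAD=0)."""
        return np.append(self.initial_distribution, 0.0)

    def effective_horizon(self) -> int:
        if self.options.horizon_mode == "to-age-90":
            return max(1, int(round(90.0 - self.initial_age)))
        return int(self.horizon_cycles)

    def diabetic_fraction(self, strategy: str, cycle: int) -> float:
        """Cohort diabetic fraction for a strategy at a given cycle.

        Usual care: everyone has diabetes for the rest of life.  Surgery:
        cycle 0 uses the pre-surgery fraction (1.0); from cycle 1 the
        12-month post-surgery fraction applies, static thereafter.
        """
        if strategy == "UC":
            return self.diabetes_fraction_uc
        return 1.0 if cycle == 0 else self.diabetes_fraction_surgery

    def class_cost_multiplier(self, cycle: int) -> np.ndarray:
        """Per-state cost multiplier for a cycle (length 4)."""
        g = np.array([0.0, 0.0, self.inflator_ob2, self.inflator_ob3])
        if self.options.class_inflator_mode == "compound":
            return (1.0 + g) ** cycle
        return 1.0 + g

    def entry_surgery_cost(self) -> float:
        """Expected first-year surgery cost over the entry distribution."""
        pi = self.initial_distribution
        return float(
            pi[HealthState.OB1] * self.surgery_cost["OB1"]
            + pi[HealthState.OB2] * self.surgery_cost["OB2"]
            + pi[HealthState.OB3] * self.surgery_cost["OB3"]
        )

    # -- functional updates -------------------------------------------
    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def with_value(self, name: str, value: float) -> "ParameterSet":
        """Return a copy with one named scalar parameter replaced.

        Names follow the PSA/DSA addressing scheme: plain field names,
        plus ``utility_<state>``, ``management_cost_<state>`` (with the
        pooled ``management_cost_ob2_ob3``), ``surgery_cost_ob1_ob2`` and
        ``surgery_cost_ob3``.
        """
        if name == "utility_ow":
            u = self.utilities.copy(); u[0] = value
            return self.replace(utilities=u)
        if name == "utility_ob1":
            u = self.utilities.copy(); u[1] = value
            return self.replace(utilities=u)
        if name == "utility_ob2":
            u = self.utilities.copy(); u[2] = value
            return self.replace(utilities=u)
        if name == "utility_ob3":
            u = self.utilities.copy(); u[3] = value
            return self.replace(utilities=u)
        if name == "management_cost_ow":
            c = self.management_cost.copy(); c[0] = value
            return self.replace(management_cost=c)
        if name == "management_cost_ob1":
            c = self.management_cost.copy(); c[1] = value
            return self.replace(management_cost=c)
        if name == "management_cost_ob2_ob3":
            c = self.management_cost.copy(); c[2] = c[3] = value
            return self.replace(management_cost=c)
        if name == "surgery_cost_ob1_ob2":
            sc = dict(self.surgery_cost); sc["OB1"] = sc["OB2"] = value
            return self.replace(surgery_cost=sc)
        if name == "surgery_cost_ob3":
            sc = dict(self.surgery_cost); sc["OB3"] = value
            return self.replace(surgery_cost=sc)
        if name == "horizon_cycles":
            return self.replace(horizon_cycles=int(round(value)))
        if hasattr(self, name):
            return self.replace(**{name: value})
        raise KeyError(f"unknown parameter name {name!r}")

    # -- serialization ------------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "initial_age": self.initial_age,
            "horizon_cycles": self.horizon_cycles,
            "discount_rate": self.discount_rate,
            "wtp": self.wtp,
            "initial_distribution": {
                k: float(v) for k, v in zip(_STATE_KEYS, self.initial_distribution)
            },
            "rr_diabetes_mortality": self.rr_diabetes_mortality,
            "surgical_mortality": self.surgical_mortality,
            "diabetes_fraction_surgery": self.diabetes_fraction_surgery,
            "diabetes_fraction_uc": self.diabetes_fraction_uc,
            "year1_surgery_transitions": copy.deepcopy(
                self.year1_surgery_transitions
            ),
            "up_surgery": self.up_surgery,
            "down_surgery": self.down_surgery,
            "up_uc": self.up_uc,
            "down_uc": self.down_uc,
            "utilities": {k: float(v) for k, v in zip(_STATE_KEYS, self.utilities)},
            "disutility_age": self.disutility_age,
            "disutility_diabetes": self.disutility_diabetes,
            "surgery_cost": {k: float(v) for k, v in self.surgery_cost.items()},
            "management_cost": {
                k: float(v) for k, v in zip(_STATE_KEYS, self.management_cost)
            },
            "inflator_ob2": self.inflator_ob2,
            "inflator_ob3": self.inflator_ob3,
            "diabetes_cost": self.diabetes_cost,
            "diabetes_cost_growth": self.diabetes_cost_growth,
            "distributions": {k: v.to_dict() for k, v in self.distributions.items()},
            "sa_ranges": {k: list(v) for k, v in self.sa_ranges.items()},
            "options": dataclasses.asdict(self.options),
        }
        return d

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


_REQUIRED_KEYS = tuple(_DEFAULTS)


def _build(config: dict) -> ParameterSet:
    dists = {
        k: DistributionSpec.from_dict(v) if isinstance(v, dict) else v
        for k, v in config.get("distributions", _DISTRIBUTIONS).items()
    }
    sa = {k: tuple(v) for k, v in config.get("sa_ranges", _SA_RANGES).items()}
    opts = config.get("options", {})
    if isinstance(opts, dict):
        opts = ModelOptions(**opts)
    return ParameterSet(
        initial_age=float(config["initial_age"]),
        horizon_cycles=int(config["horizon_cycles"]),
        discount_rate=float(config["discount_rate"]),
        wtp=float(config["wtp"]),
        initial_distribution=_as_state_vector(
            config["initial_distribution"], "initial_distribution"
        ),
        rr_diabetes_mortality=float(config["rr_diabetes_mortality"]),
        surgical_mortality=float(config["surgical_mortality"]),
        diabetes_fraction_surgery=float(config["diabetes_fraction_surgery"]),
        diabetes_fraction_uc=float(config["diabetes_fraction_uc"]),
        year1_surgery_transitions={
            o: {d: float(p) for d, p in row.items()}
            for o, row in config["year1_surgery_transitions"].items()
        },
        up_surgery=float(config["up_surgery"]),
        down_surgery=float(config["down_surgery"]),
        up_uc=float(config["up_uc"]),
        down_uc=float(config["down_uc"]),
        utilities=_as_state_vector(config["utilities"], "utilities"),
        disutility_age=float(config["disutility_age"]),
        disutility_diabetes=float(config["disutility_diabetes"]),
        surgery_cost={k: float(v) for k, v in config["surgery_cost"].items()},
        management_cost=_as_state_vector(
            config["management_cost"], "management_cost"
        ),
        inflator_ob2=float(config["inflator_ob2"]),
        inflator_ob3=float(config["inflator_ob3"]),
        diabetes_cost=float(config["diabetes_cost"]),
        diabetes_cost_growth=float(config["diabetes_cost_growth"]),
        distributions=dists,
        sa_ranges=sa,
        options=opts,
    )


def load_parameters(source=None) -> ParameterSet:
    """Load a :class:`ParameterSet` from a config mapping or YAML file.

    ``source`` may be None (packaged defaults), a path to a YAML/JSON
    file, or a mapping.  A mapping with ``use_defaults: true`` overrides
    individual keys on top of the defaults; without it, every required
    key must be present.
    """
    if source is None:
        return _build(copy.deepcopy(_DEFAULTS))
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            config = yaml.safe_load(fh) or {}
    else:
        config = copy.deepcopy(dict(source))
    use_defaults = bool(config.pop("use_defaults", False))
    if use_defaults:
        merged = copy.deepcopy(_DEFAULTS)
        for key, value in config.items():
            if isinstance(value, dict) and isinstance(merged.get(key), dict):
                merged[key] = {**merged[key], **value}
            else:
                merged[key] = value
        config = merged
    missing = [k for k in _REQUIRED_KEYS if k not in config]
    if missing:
        raise ConfigurationError(
            f"configuration missing required key(s): {missing}; "
            "set use_defaults: true to fill from the packaged defaults"
        )
    return _build(config)


def default_parameters(**overrides) -> ParameterSet:
    """Packaged point-estimate parameters, optionally with field overrides."""
    params = load_parameters(None)
    return params.replace(**overrides) if overrides else params


def default_lifetable(max_age: int = 90) -> LifeTable:
    """Gompertz life table through the packaged anchor rates.

    Tabulated to ``max_age`` (default 90); the engine's lookups clamp
    beyond the final age, holding the age-90 hazard for older cycles.
    """
    return build_lifetable(DEFAULT_ANCHORS, max_age=max_age)
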