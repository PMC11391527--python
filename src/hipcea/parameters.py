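"""Model inputs: the base-case parameter set and the background life table.

All quantities are annual. Costs are in 2020 US dollars, utilities on the
usual 0 (death) to 1 (full health) QALY scale. The base-case values describe
an 80-year-old cohort with a nondisplaced femoral neck fracture treated with
either internal fixation (IF) or hemiarthroplasty (HA); failed implants are
salvaged by conversion arthroplasty (HA or THA).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

__all__ = [
    "ModelParams",
    "LifeTable",
    "ConfigError",
    "ValidationError",
    "load_params",
    "dump_params",
    "load_lifetable",
    "default_lifetable",
    "mortality_at_age",
]


class ConfigError(ValueError):
    """A configuration document is missing or unparseable."""


class ValidationError(ValueError):
    """A parameter value violates its admissible range."""


# (field, lower bound, upper bound) — bounds are inclusive.
_BOUNDS = {
    "periop_mort_if": (0.0, 1.0),
    "periop_mort_ha": (0.0, 1.0),
    "periop_mort_tha": (0.0, 1.0),
    "fail_if": (0.0, 1.0),
    "fail_ha": (0.0, 1.0),
    "conv_split_if_to_ha": (0.0, 1.0),
    "u_if": (0.0, 1.0),
    "u_ha": (0.0, 1.0),
    "u_tha": (0.0, 1.0),
    "disutil_salvage": (-1.0, 0.0),
    "c_if": (0.0, None),
    "c_ha": (0.0, None),
    "c_if_to_ha": (0.0, None),
    "c_if_to_tha": (0.0, None),
    "c_ha_to_tha": (0.0, None),
    "wtp": (0.0, None),
    "discount_rate": (0.0, None),
}


@dataclass(frozen=True)
class ModelParams:
    """Every scalar input of the decision model, defaulted to the base case.

    The record is immutable; derive variants with :func:`dataclasses.replace`
    (re-validation runs automatically).
    """

    # perioperative (one-off, at surgery) death probabilities per procedure
    periop_mort_if: float = 0.041
    periop_mort_ha: float = 0.053
    periop_mort_tha: float = 0.039
    # annual implant failure probabilities; a salvage HA fails like a primary HA
    fail_if: float = 0.033
    fail_ha: float = 0.015
    # share of IF failures salvaged with HA (remainder go straight to THA)
    conv_split_if_to_ha: float = 0.5
    # health-state utilities (QALY weight per year lived in the state)
    u_if: float = 0.63
    u_ha: float = 0.68
    u_tha: float = 0.70
    # one-off QALY decrement in the cycle of a conversion procedure
    disutil_salvage: float = -0.15
    # costs, 2020 USD
    c_if: float = 8_632.0
    c_ha: float = 12_449.0
    c_if_to_ha: float = 26_670.0
    c_if_to_tha: float = 25_508.0
    c_ha_to_tha: float = 22_662.0
    # decision context
    wtp: float = 11_083.0
    discount_rate: float = 0.03
    horizon_cycles: int = 5
    start_age: int = 80

    def __post_init__(self) -> None:
        for name, (lo, hi) in _BOUNDS.items():
            v = getattr(self, name)
            if not isinstance(v, (int, float)) or isinstance(v, bool):
                raise ValidationError(f"{name}: expected a number, got {v!r}")
            if lo is not None and v < lo:
                raise ValidationError(f"{name}={v} below lower bound {lo}")
            if hi is not None and v > hi:
                raise ValidationError(f"{name}={v} above upper bound {hi}")
        if not isinstance(self.horizon_cycles, int) or self.horizon_cycles < 1:
            raise ValidationError(
                f"horizon_cycles={self.horizon_cycles} must be an integer >= 1"
            )
        if not isinstance(self.start_age, int) or self.start_age < 0:
            raise ValidationError(f"start_age={self.start_age} must be a nonnegative integer")

    def replace(self, **changes) -> "ModelParams":
        """Return a validated copy with the given fields replaced."""
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_FIELD_NAMES = {f.name for f in dataclasses.fields(ModelParams)}
_INT_FIELDS = {"horizon_cycles", "start_age"}


def load_params(source) -> ModelParams:
    """Build a validated :class:`ModelParams` from a config document.

    ``source`` may be a mapping, a YAML/JSON string, or a path to a YAML/JSON
    file. Keys override the base-case defaults; unknown keys raise a warning
    and are ignored.
    """
    if isinstance(source, ModelParams):
        return source
    if isinstance(source, Mapping):
        doc = dict(source)
    else:
        if isinstance(source, Path) or (
            isinstance(source, str) and "\n" not in source and source.endswith(
                (".yaml", ".yml", ".json")
            )
        ):
            path = Path(source)
            if not path.exists():
                raise ConfigError(f"config file not found: {path}")
            text = path.read_text()
        else:
            text = str(source)
        try:
            doc = yaml.safe_load(text) or {}
        except yaml.YAMLError as exc:  # YAML is a superset of JSON
            raise ConfigError(f"could not parse config document: {exc}") from exc
        if not isinstance(doc, Mapping):
            raise ConfigError("config document must be a mapping of parameter names")
        doc = dict(doc)

    unknown = sorted(set(doc) - _FIELD_NAMES)
    if unknown:
        warnings.warn(f"ignoring unknown config keys: {', '.join(unknown)}", stacklevel=2)
        for k in unknown:
            doc.pop(k)
    for k in _INT_FIELDS & set(doc):
        doc[k] = int(doc[k])
    return ModelParams(**doc)


def dump_params(params: ModelParams, path=None) -> str:
    """Serialize a parameter set to YAML; write to ``path`` when given."""
    text = yaml.safe_dump(params.to_dict(), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed annual probability of death from other (background) causes."""

    entries: tuple = field(default=())  # ((age, qx), ...) ages strictly increasing

    def __post_init__(self) -> None:
        ages = [a for a, _ in self.entries]
        if ages != sorted(set(ages)):
            raise ValidationError("life table ages must be strictly increasing")
        for age, q in self.entries:
            if not 0.0 <= q <= 1.0:
                raise ValidationError(f"life table qx at age {age} is {q}, outside [0, 1]")

    @classmethod
    def from_mapping(cls, mapping: Mapping[int, float]) -> "LifeTable":
        return cls(tuple(sorted((int(a), float(q)) for a, q in mapping.items())))

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path, comment="#")
        if not {"age", "qx"} <= set(df.columns):
            raise ConfigError(f"life table {path} must have columns 'age,qx'")
        return cls.from_mapping(dict(zip(df["age"].astype(int), df["qx"].astype(float))))

    def to_csv(self, path) -> None:
        pd.DataFrame(self.entries, columns=["age", "qx"]).to_csv(path, index=False)

    @property
    def ages(self) -> tuple:
        return tuple(a for a, _ in self.entries)

    def covers(self, ages: Iterable[int]) -> bool:
        have = set(self.ages)
        return all(a in have for a in ages)

    def mortality_at(self, age: int) -> float:
        for a, q in self.entries:
            if a == age:
                return q
        raise LookupError(
            f"age {age} outside life table coverage "
            f"[{self.ages[0] if self.entries else '?'}, "
            f"{self.ages[-1] if self.entries else '?'}]; no extrapolation is performed"
        )


def mortality_at_age(table: LifeTable, age: int) -> float:
    """Tabulated annual background death probability at ``age`` (no extrapolation)."""
    return table.mortality_at(age)


def load_lifetable(path) -> LifeTable:
    return LifeTable.from_csv(path)


def default_lifetable() -> LifeTable:
    """The bundled Chinese 2020 census life-table fixture (ages 80-85)."""
    ref = resources.files("hipcea").joinpath("data/china_census_2020_lifetable.csv")
    with resources.as_file(ref) as path:
        return LifeTable.from_csv(path)
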