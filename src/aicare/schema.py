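"""Feature schema for the peritoneal-dialysis follow-up panel.

The default panel is the 16-feature laboratory/vital-sign set recorded at
each clinic visit plus 4 baseline (static) features recorded once at the
start of dialysis. Plausible ranges are wide physiologic bounds used only
for validation, not for clipping model inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import yaml

__all__ = ["FeatureDescriptor", "FeatureSchema", "default_pd_schema"]


@dataclass(frozen=True)
class FeatureDescriptor:
    """One feature: its name, measurement unit and plausible numeric range."""

    name: str
    unit: str
    lower: float
    upper: float
    binary: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("feature name must be nonempty")
        if not self.lower < self.upper:
            raise ValueError(f"{self.name}: plausible range needs lower < upper")


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered dynamic (per-visit) and static (baseline) feature descriptors."""

    dynamic_features: tuple[FeatureDescriptor, ...]
    static_features: tuple[FeatureDescriptor, ...]

    def __post_init__(self) -> None:
        names = [f.name for f in self.dynamic_features] + [
            f.name for f in self.static_features
        ]
        if len(set(names)) != len(names):
            raise ValueError("feature names must be unique across the schema")
        if not self.dynamic_features:
            raise ValueError("at least one dynamic feature required")
        if not self.static_features:
            raise ValueError("at least one static feature required")

    @property
    def dynamic_names(self) -> list[str]:
        return [f.name for f in self.dynamic_features]

    @property
    def static_names(self) -> list[str]:
        return [f.name for f in self.static_features]

    @property
    def n_dynamic(self) -> int:
        return len(self.dynamic_features)

    def dynamic(self, name: str) -> FeatureDescriptor:
        for f in self.dynamic_features:
            if f.name == name:
                return f
        raise KeyError(name)

    def to_yaml(self, path) -> None:
        doc = {
            "dynamic_features": [
                {"name": f.name, "unit": f.unit, "lower": f.lower, "upper": f.upper}
                for f in self.dynamic_features
            ],
            "static_features": [
                {
                    "name": f.name,
                    "unit": f.unit,
                    "lower": f.lower,
                    "upper": f.upper,
                    "binary": f.binary,
                }
                for f in self.static_features
            ],
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "FeatureSchema":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh)
        return cls(
            dynamic_features=tuple(
                FeatureDescriptor(
                    d["name"], d.get("unit", ""), d["lower"], d["upper"],
                    d.get("binary", False),
                )
                for d in doc["dynamic_features"]
            ),
            static_features=tuple(
                FeatureDescriptor(
                    d["name"], d.get("unit", ""), d["lower"], d["upper"],
                    d.get("binary", False),
                )
                for d in doc["static_features"]
            ),
        )


# (name, unit, plausible lower, plausible upper)
_PD_DYNAMIC: tuple[tuple[str, str, float, float], ...] = (
    ("albumin", "g/L", 10.0, 60.0),
    ("dbp", "mm Hg", 20.0, 140.0),
    ("sbp", "mm Hg", 50.0, 260.0),
    ("cl", "mmol/L", 70.0, 130.0),
    ("cr", "umol/L", 50.0, 2500.0),
    ("urea", "mmol/L", 1.0, 60.0),
    ("ca", "mmol/L", 1.0, 4.0),
    ("na", "mmol/L", 110.0, 170.0),
    ("k", "mmol/L", 1.5, 8.0),
    ("p", "mmol/L", 0.3, 4.0),
    ("co2cp", "mmol/L", 5.0, 45.0),
    ("hb", "g/L", 30.0, 200.0),
    ("weight", "kg", 25.0, 150.0),
    ("glucose", "mmol/L", 1.0, 35.0),
    ("hscrp", "mg/L", 0.0, 300.0),
    ("wbc", "1e9/L", 0.5, 40.0),
)

_PD_STATIC: tuple[tuple[str, str, float, float, bool], ...] = (
    ("age", "year", 16.0, 98.0, False),
    ("gender", "0=female,1=male", 0.0, 1.0001, True),
    ("height", "cm", 120.0, 200.0, False),
    ("diabetes", "0/1", 0.0, 1.0001, True),
)


def default_pd_schema() -> FeatureSchema:
    """The default 16-dynamic / 4-static peritoneal-dialysis panel."""
    return FeatureSchema(
        dynamic_features=tuple(FeatureDescriptor(*row) for row in _PD_DYNAMIC),
        static_features=tuple(FeatureDescriptor(*row) for row in _PD_STATIC),
    )


def validate_names(schema: FeatureSchema, names: Iterable[str]) -> None:
    known = set(schema.dynamic_names)
    unknown = [n for n in names if n not in known]
    if unknown:
        raise KeyError(f"unknown dynamic feature(s): {unknown}")
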