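"""Allometric body-mass reconstruction for extinct archosaurs.

Body masses of fossil taxa cannot be weighed, so they are reconstructed
from skeletal measurements through published allometric scaling relations.
Two chains are implemented:

* the pterosaur chain — cumulative wing-element length plus an
  interglenoid distance inferred from humeral length yields a wingspan,
  from which a span–mass power law predicts body mass;
* generic power-law / log-log relations (e.g. crocodylian total body
  length to mass) applied directly.

The regression coefficients are not authored here: they ship as registry
entries carrying their citation, validated against the printed
reconstructions they must reproduce, and can be corrected from the
registry file without a code change.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

__all__ = [
    "WingMeasurements",
    "AllometricRelation",
    "load_relations",
    "total_wing_length",
    "interglenoid_distance",
    "wingspan",
    "predict_mass",
    "pterosaur_mass_chain",
]

#: Canonical element order of the pterosaur wing skeleton.
WING_ELEMENTS = (
    "humerus",
    "radius",
    "wing_metacarpal",
    "phalanx_1",
    "phalanx_2",
    "phalanx_3",
    "phalanx_4",
)


@dataclass(frozen=True)
class WingMeasurements:
    """Lengths (mm) of the seven wing elements plus glenoid geometry."""

    element_lengths: dict[str, float]
    glenoid_ratio: float = 1.56  # interglenoid distance / humeral length

    def __post_init__(self) -> None:
        for name, length in self.element_lengths.items():
            if not length > 0:
                raise ValueError(f"element length must be positive: {name}={length}")
        if not self.glenoid_ratio > 0:
            raise ValueError("glenoid ratio must be positive")

    @property
    def humerus_length(self) -> float:
        return self.element_lengths["humerus"]


@dataclass(frozen=True)
class AllometricRelation:
    """One mass-prediction relation, mass = a * x**b (or its log-log form)."""

    name: str
    kind: str  # "power-law" | "log-log linear"
    a: float
    b: float
    x_definition: str
    x_range: tuple[float, float] | None = None  # calibration envelope
    source: str = ""

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError("amplitude a must be positive")
        if not self.b > 0:
            raise ValueError("exponent b must be positive (prediction must be monotone)")

    def predict(self, x: float) -> float:
        """Predicted body mass in grams for predictor value ``x``."""
        if not x > 0:
            raise ValueError(f"predictor must be positive, got {x}")
        if self.kind == "log-log linear":
            return 10.0 ** (math.log10(self.a) + self.b * math.log10(x))
        return self.a * x**self.b


def load_relations(path: str | Path | None = None) -> dict[str, AllometricRelation]:
    """Load the allometric-relations registry (the shipped one by default)."""
    if path is None:
        text = (
            resources.files("wingbeam.data")
            .joinpath("allometric_relations.json")
            .read_text()
        )
    else:
        text = Path(path).read_text()
    entries = json.loads(text)
    registry = {}
    for e in entries:
        rel = AllometricRelation(
            name=e["name"],
            kind=e["kind"],
            a=e["a"],
            b=e["b"],
            x_definition=e["x_definition"],
            x_range=tuple(e["x_range"]) if e.get("x_range") else None,
            source=e.get("source", ""),
        )
        registry[rel.name] = rel
    return registry


def total_wing_length(measurements: WingMeasurements) -> float:
    """Cumulative length (mm) of the seven wing elements."""
    missing = [e for e in WING_ELEMENTS if e not in measurements.element_lengths]
    if missing:
        raise ValueError(f"missing wing elements: {missing}")
    return float(sum(measurements.element_lengths[e] for e in WING_ELEMENTS))


def interglenoid_distance(
    humerus_length: float, glenoid_ratio: float, *, report_rounding: bool = False
) -> float:
    """Distance between left and right glenoid, mm.

    With ``report_rounding`` the result is rounded to the nearest mm as in
    conventional osteometric reporting.
    """
    if not humerus_length > 0 or not glenoid_ratio > 0:
        raise ValueError("humerus length and glenoid ratio must be positive")
    d = humerus_length * glenoid_ratio
    return float(round(d)) if report_rounding else d


def wingspan(wing_length_mm: float, interglenoid_mm: float) -> float:
    """Wingspan in metres: twice the wing length plus the interglenoid distance."""
    if not wing_length_mm > 0 or interglenoid_mm < 0:
        raise ValueError("wing length must be positive and interglenoid non-negative")
    return (2.0 * wing_length_mm + interglenoid_mm) / 1000.0


def predict_mass(relation: AllometricRelation, x: float) -> float:
    """Body mass (g) from a registry relation; warns outside its calibration range."""
    if relation.x_range is not None and not (
        relation.x_range[0] <= x <= relation.x_range[1]
    ):
        import warnings

        warnings.warn(
            f"{relation.name}: predictor {x} outside calibration range "
            f"{relation.x_range}",
            stacklevel=2,
        )
    return relation.predict(x)


def pterosaur_mass_chain(
    measurements: WingMeasurements,
    relation: AllometricRelation,
    *,
    report_rounding: bool = True,
) -> dict[str, float]:
    """Run the full pterosaur reconstruction chain.

    Returns every intermediate: total wing length (mm), interglenoid
    distance (mm), wingspan (m) and predicted body mass (g).
    """
    wl = total_wing_length(measurements)
    ig = interglenoid_distance(
        measurements.humerus_length,
        measurements.glenoid_ratio,
        report_rounding=report_rounding,
    )
    span = wingspan(wl, ig)
    mass = predict_mass(relation, span)
    return {
        "total_wing_length_mm": wl,
        "interglenoid_mm": ig,
        "wingspan_m": span,
        "mass_g": mass,
    }
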