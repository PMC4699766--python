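"""Target-volume geometry: the flattened endothelial nucleus and the DNA cylinder.

Adherent HUVEC nuclei are well described by an elliptic cylinder (full major
axis ~17 um, full minor axis ~11 um, thickness ~2 um, giving ~293.7 um^3),
while a stretched-out 6-Gbp DNA molecule is idealized as a thin cylinder
(diameter 2.3 nm, length 2.04 m, giving ~8.5 um^3).  All volumes are reported
in um^3; lengths carry explicit unit tags that are normalized before any
arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "NucleusGeometry",
    "CylinderGeometry",
    "elliptic_cylinder_volume",
    "cylinder_volume",
    "volume_fraction",
    "to_um",
]

# length-unit scale factors to micrometres
_UM_PER = {"nm": 1e-3, "um": 1.0, "mm": 1e3, "m": 1e6}


def to_um(value: float, unit: str) -> float:
    """Convert a length to micrometres; unknown unit tags raise."""
    try:
        return value * _UM_PER[unit]
    except KeyError:
        raise ValueError(f"unknown length unit {unit!r}; expected one of {sorted(_UM_PER)}") from None


@dataclass(frozen=True)
class NucleusGeometry:
    """Elliptic-cylinder nucleus; axes are full axis lengths in um."""

    major_axis: float
    minor_axis: float
    thickness: float

    def __post_init__(self) -> None:
        for name in ("major_axis", "minor_axis", "thickness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.major_axis < self.minor_axis:
            raise ValueError("major_axis must be >= minor_axis")


@dataclass(frozen=True)
class CylinderGeometry:
    """Circular cylinder with unit-tagged dimensions."""

    diameter: float
    length: float
    diameter_unit: str = "um"
    length_unit: str = "um"

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("diameter and length must be > 0")
        for u in (self.diameter_unit, self.length_unit):
            if u not in _UM_PER:
                raise ValueError(f"unknown length unit {u!r}")


def elliptic_cylinder_volume(g: NucleusGeometry) -> float:
    """Volume pi * (major/2) * (minor/2) * thickness, in um^3."""
    return float(np.pi * (g.major_axis / 2) * (g.minor_axis / 2) * g.thickness)


def cylinder_volume(g: CylinderGeometry) -> float:
    """Volume pi * (d/2)^2 * L after normalizing both lengths to um."""
    d = to_um(g.diameter, g.diameter_unit)
    length = to_um(g.length, g.length_unit)
    return float(np.pi * (d / 2) ** 2 * length)


def volume_fraction(v_sub: float, v_total: float) -> float:
    """Fraction of the total volume occupied by a sub-volume."""
    if v_sub <= 0 or v_total <= 0:
        raise ValueError("volumes must be > 0")
    return v_sub / v_total


#: Default HUVEC nucleus (um): full axes 17 x 11, thickness 2 -> 293.7 um^3.
HUVEC_NUCLEUS = NucleusGeometry(major_axis=17.0, minor_axis=11.0, thickness=2.0)

#: 6-Gbp DNA molecule as a cylinder: 2.3 nm diameter, 2.04 m length -> 8.5 um^3.
DNA_CYLINDER = CylinderGeometry(diameter=2.3, length=2.04, diameter_unit="nm", length_unit="m")
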