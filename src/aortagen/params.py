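"""The aorta symbol table: one parameter set fully defines an idealized aorta.

All lengths are centimetres, angles degrees; the coronary diameters ``C1``
and ``C2`` are millimetres (they are an order of magnitude smaller than the
arch vessels and are conventionally reported in mm).

Two arch variants are supported.  The Normal (Type I) arch carries three
branches — brachiocephalic (BA), left common carotid (LCA) and left
subclavian (LSA) — with diameters ``phi1..phi3``, takeoff angles
``alpha1..alpha3`` and spacings ``d1`` (BA–LCA), ``d2`` (LCA–LSA).  The
Bovine (Type II) arch carries a common brachiocephalic/carotid trunk
(``phib1``, ``alphab1``) and the LSA (``phib2``, ``alphab2``) separated by
``d3``.  Symbols of the other variant are ``None``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from enum import Enum
from pathlib import Path
from typing import Any

import yaml

from .errors import ParameterError


class ArchType(str, Enum):
    """Aortic arch branching variant."""

    TYPE_I = "TypeI"    # Normal: BA, LCA, LSA off the arch
    TYPE_II = "TypeII"  # Bovine: common BA+LCA trunk, then LSA

    @classmethod
    def coerce(cls, value: "ArchType | str") -> "ArchType":
        if isinstance(value, cls):
            return value
        norm = str(value).strip().lower().replace("_", "").replace(" ", "")
        aliases = {
            "typei": cls.TYPE_I, "i": cls.TYPE_I, "1": cls.TYPE_I, "normal": cls.TYPE_I,
            "typeii": cls.TYPE_II, "ii": cls.TYPE_II, "2": cls.TYPE_II, "bovine": cls.TYPE_II,
        }
        try:
            return aliases[norm]
        except KeyError:
            raise ParameterError(f"unknown arch type: {value!r}") from None


# symbols that must be present (non-None) / absent (None) per variant
_TYPE_I_ONLY = ("d1", "d2", "phi1", "phi2", "phi3", "alpha1", "alpha2", "alpha3")
_TYPE_II_ONLY = ("d3", "phib1", "phib2", "alphab1", "alphab2")

_LENGTHS = ("D1", "D2", "D3", "root_diameter", "proximal_descending_diameter",
            "H", "W", "R", "L", "a", "d1", "d2", "d3",
            "phi1", "phi2", "phi3", "phib1", "phib2", "C1", "C2")
_ANGLES = ("alpha1", "alpha2", "alpha3", "alphab1", "alphab2")


@dataclass(frozen=True)
class AortaParameterSet:
    """Full symbol table for one idealized aorta (cm / degrees / mm for C*)."""

    arch_type: ArchType
    D1: float   # ascending aorta diameter [cm]
    D2: float   # aortic arch diameter [cm]
    D3: float   # mid-descending aorta diameter [cm]
    H: float    # arch height in the parasagittal plane [cm]
    W: float    # arch width in the parasagittal plane [cm]
    R: float    # transverse-plane arch bend radius [cm]
    L: float    # sinotubular junction -> start of arch [cm]
    a: float    # sinotubular junction -> first arch branch, along centerline [cm]
    C1: float   # right coronary diameter [mm]
    C2: float   # left coronary diameter [mm]
    beta1: float = 0.0  # descending tilt from vertical [deg]
    beta2: float = 0.0  # descending twist, posterior toward left [deg]
    beta3: float = 0.0  # arch transverse rotation toward posterior-left [deg]
    root_diameter: float | None = None                 # reported only
    proximal_descending_diameter: float | None = None  # reported only
    d1: float | None = None      # BA–LCA spacing (Type I) [cm]
    d2: float | None = None      # LCA–LSA spacing (Type I) [cm]
    d3: float | None = None      # trunk–LSA spacing (Type II) [cm]
    phi1: float | None = None    # BA diameter (Type I) [cm]
    phi2: float | None = None    # LCA diameter (Type I) [cm]
    phi3: float | None = None    # LSA diameter (Type I) [cm]
    phib1: float | None = None   # common trunk diameter (Type II) [cm]
    phib2: float | None = None   # LSA diameter (Type II) [cm]
    alpha1: float | None = None  # BA takeoff angle (Type I) [deg]
    alpha2: float | None = None  # LCA takeoff angle (Type I) [deg]
    alpha3: float | None = None  # LSA takeoff angle (Type I) [deg]
    alphab1: float | None = None  # trunk takeoff angle (Type II) [deg]
    alphab2: float | None = None  # LSA takeoff angle (Type II) [deg]

    def __post_init__(self) -> None:
        object.__setattr__(self, "arch_type", ArchType.coerce(self.arch_type))
        self.validate()

    # -- derived ---------------------------------------------------------
    @property
    def hw_ratio(self) -> float:
        """Arch height-to-width ratio H/W (elongation marker)."""
        return self.H / self.W

    @property
    def branch_symbols(self) -> tuple[str, ...]:
        """Diameter symbols of the arch branches, proximal to distal."""
        if self.arch_type is ArchType.TYPE_I:
            return ("phi1", "phi2", "phi3")
        return ("phib1", "phib2")

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for name in _LENGTHS:
            v = getattr(self, name)
            if v is not None and not v > 0:
                raise ParameterError(f"{name} must be positive, got {v}")
        for name in _ANGLES:
            v = getattr(self, name)
            if v is not None and not 0 < v < 180:
                raise ParameterError(f"{name} must lie in (0, 180) deg, got {v}")
        for name in ("beta1", "beta2", "beta3"):
            v = getattr(self, name)
            if not -180 < v < 180:
                raise ParameterError(f"{name} must lie in (-180, 180) deg, got {v}")
        if not self.D1 > self.D2:
            raise ParameterError(
                f"ascending diameter D1 ({self.D1}) must exceed arch diameter D2 ({self.D2})")
        required = _TYPE_I_ONLY if self.arch_type is ArchType.TYPE_I else _TYPE_II_ONLY
        absent = _TYPE_II_ONLY if self.arch_type is ArchType.TYPE_I else _TYPE_I_ONLY
        for name in required:
            if getattr(self, name) is None:
                raise ParameterError(f"{self.arch_type.value} requires {name}")
        for name in absent:
            if getattr(self, name) is not None:
                raise ParameterError(f"{name} does not apply to {self.arch_type.value}")

    # -- convenience -----------------------------------------------------
    def with_overrides(self, **overrides: Any) -> "AortaParameterSet":
        """Return a copy with the given symbols replaced (and re-validated)."""
        unknown = set(overrides) - {f.name for f in fields(self)}
        if unknown:
            raise ParameterError(f"unknown parameter symbol(s): {sorted(unknown)}")
        return replace(self, **overrides)

    def scaled(self, factor: float) -> "AortaParameterSet":
        """Uniformly scale every length; angles are untouched."""
        if not factor > 0:
            raise ParameterError("scale factor must be positive")
        updates = {}
        for name in _LENGTHS:
            v = getattr(self, name)
            if v is not None:
                updates[name] = v * factor
        return replace(self, **updates)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"arch_type": self.arch_type.value}
        for f in fields(self):
            if f.name == "arch_type":
                continue
            out[f.name] = getattr(self, f.name)
        return out

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "AortaParameterSet":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter symbol(s): {sorted(unknown)}")
        if "arch_type" not in data:
            raise ParameterError("parameter set must name an arch_type")
        return cls(**data)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        text = (json.dumps(self.to_dict(), indent=2) if path.suffix == ".json"
                else yaml.safe_dump(self.to_dict(), sort_keys=False))
        path.write_text(text)

    @classmethod
    def load(cls, path: str | Path) -> "AortaParameterSet":
        path = Path(path)
        data = (json.loads(path.read_text()) if path.suffix == ".json"
                else yaml.safe_load(path.read_text()))
        if not isinstance(data, dict):
            raise ParameterError(f"{path} does not contain a parameter mapping")
        return cls.from_dict(data)
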