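"""Closed-form pipe-flow helpers for the LVAD inflow conditions.

Blood is treated as a Newtonian fluid (density 1060 kg/m^3, dynamic
viscosity 0.004 Pa.s).  For a cannula of diameter D carrying a volumetric
flow Q, the bulk velocity is U = Q / (pi D^2 / 4) and the Reynolds number
Re = rho U D / mu = 4 rho Q / (pi mu D).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError

__all__ = ["FlowCondition", "bulk_velocity", "reynolds"]

LPM_TO_M3S = 1e-3 / 60.0


@dataclass(frozen=True)
class FlowCondition:
    """Steady inflow condition through a circular cannula."""

    Q: float              # volumetric flow [L/min]
    D: float              # cannula diameter [mm]
    rho: float = 1060.0   # blood density [kg/m^3]
    mu: float = 0.004     # blood dynamic viscosity [Pa.s]

    def __post_init__(self) -> None:
        if self.Q < 0:
            raise ParameterError("flow rate must be non-negative")
        for name in ("D", "rho", "mu"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")


def bulk_velocity(cond: FlowCondition) -> float:
    """Cross-section-averaged velocity U = Q / (pi D^2 / 4) in m/s."""
    area = math.pi * (cond.D * 1e-3) ** 2 / 4.0
    return cond.Q * LPM_TO_M3S / area


def reynolds(cond: FlowCondition) -> float:
    """Reynolds number rho U D / mu of the cannula inflow."""
    return cond.rho * bulk_velocity(cond) * (cond.D * 1e-3) / cond.mu
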