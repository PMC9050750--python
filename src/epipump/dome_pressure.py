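"""Dome hydrostatic pressure from micro-needle interface curvature.

Fluid-filled epithelial domes on impermeable substrates hold an excess
hydrostatic pressure.  Inserting an oil-filled micro-needle and reading
the radius of curvature R of the oil-media meniscus gives that pressure
through the Young-Laplace law, P2 - P1 = 2 gamma / R for a spherical
meniscus (gamma the oil-media interfacial tension).  The Laplace law for
the dome shell itself, T = P R_dome / 2, converts the pressure into a
wall tension given the dome radius.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pump_model import ConfigurationError

__all__ = ["DomeMeasurement", "laplace_pressure", "dome_tension"]


@dataclass(frozen=True)
class DomeMeasurement:
    """One meniscus reading: curvature radius (m), interfacial tension
    (N/m), optional dome radius (m), reference port pressure (Pa gauge)."""

    R_interface: float
    gamma: float
    R_dome: float | None = None
    P_ref: float = 0.0

    def __post_init__(self):
        if self.R_interface <= 0:
            raise ConfigurationError("R_interface must be > 0")
        if self.gamma <= 0:
            raise ConfigurationError("gamma must be > 0")


def laplace_pressure(m: DomeMeasurement, *, spherical: bool = True) -> float:
    """Dome hydrostatic pressure (Pa) from the meniscus curvature.

    Spherical-cap meniscus by default (2 gamma / R); ``spherical=False``
    uses the cylindrical form (gamma / R).  The needle-port reference
    pressure is added.
    """
    factor = 2.0 if spherical else 1.0
    return factor * m.gamma / m.R_interface + m.P_ref


def dome_tension(P: float, R_dome: float) -> float:
    """Dome wall tension (N/m) by the shell Laplace law T = P R / 2."""
    if P < 0 or R_dome <= 0:
        raise ConfigurationError("P must be >= 0 and R_dome > 0")
    return P * R_dome / 2.0
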