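"""Microfluidic device mathematics: heights -> pressures -> fluxes -> PPCs.

The device reads trans-epithelial pumping as the rise of a fluid column
in a microcapillary glued to a mm ruler: the column height gives the
hydrostatic head (rho g h, minus a per-device capillary-action offset
obtained from blank calibration), and the slope of the height trace
times the capillary cross-section gives the volume flux.  Pairing the
instantaneous head with the instantaneous flux along one filling trace
reconstructs the pump performance curve of the monolayer in the device.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .pump_model import ConfigurationError, PPCCurve

__all__ = [
    "DeviceGeometry",
    "CapillaryTrace",
    "pressure_from_height",
    "flux_from_trace",
    "ppc_from_trace",
    "shear_to_flow",
    "flow_to_shear",
    "device_resolution",
    "STANDARD_GRAVITY",
]

log = logging.getLogger(__name__)

STANDARD_GRAVITY = 9.81  # m s^-2


@dataclass(frozen=True)
class DeviceGeometry:
    """Geometry of the microfluidic kidney-pump device.

    A_mc : microcapillary cross-section (mm^2, 0.31 mm^2 gives the
    quoted 0.31 uL volume resolution per 1 mm graduation); A_epi :
    epithelium area exposed in the device (mm^2, 6 mm x 2 mm);
    capillary_offset : pressure contribution of capillary action (Pa)
    from blank calibration; channel_width/height : apical channel
    section (mm).
    """

    A_mc: float = 0.31
    ruler_resolution: float = 1.0
    capillary_offset: float = 0.0
    A_epi: float = 12.0
    channel_width: float = 2.0
    channel_height: float = 0.25

    def __post_init__(self):
        for name in ("A_mc", "ruler_resolution", "A_epi", "channel_width", "channel_height"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.capillary_offset < 0:
            raise ConfigurationError("capillary_offset must be >= 0")


@dataclass(frozen=True)
class CapillaryTrace:
    """Timestamped column heights from one device run.

    t in seconds (strictly increasing), h in mm, ``setup`` names which
    port the capillary is on (S1: basal column, absorptive runs; S2:
    apical column, secretory runs), rho is the medium density.
    """

    t: np.ndarray
    h: np.ndarray
    setup: Literal["S1", "S2"] = "S1"
    rho: float = 1020.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        t = np.asarray(self.t, dtype=float)
        h = np.asarray(self.h, dtype=float)
        if t.ndim != 1 or t.shape != h.shape or t.size < 2:
            raise ConfigurationError("trace needs matching 1-D t and h with >= 2 samples")
        if not np.all(np.diff(t) > 0):
            raise ConfigurationError("time points must be strictly increasing")
        if self.setup not in ("S1", "S2"):
            raise ConfigurationError(f"unknown setup {self.setup!r}")
        if self.rho <= 0:
            raise ConfigurationError("rho must be > 0")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "h", h)

    def __len__(self) -> int:
        return self.t.size


def pressure_from_height(
    h_mm: float | np.ndarray,
    rho: float = 1020.0,
    g: float = STANDARD_GRAVITY,
    offset: float = 0.0,
) -> float | np.ndarray:
    """Gauge pressure (Pa) of a column of height h (mm): rho g h - offset.

    A negative result is a head below the capillary-action reference and
    is allowed but logged.
    """
    p = rho * g * np.asarray(h_mm, dtype=float) * 1e-3 - offset
    if np.any(np.asarray(p) < 0):
        log.warning("pressure_from_height produced negative gauge pressure(s)")
    return p if np.ndim(h_mm) else float(p)


def _rolling_slopes(t: np.ndarray, h: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares slope of h vs t in each sliding window.

    Returns (slopes, center indices).  Windowed regression rather than
    finite differences because readings are quantised to the ruler
    graduation.
    """
    n = t.size - window + 1
    slopes = np.empty(n)
    for i in range(n):
        ts = t[i : i + window]
        hs = h[i : i + window]
        tc = ts - ts.mean()
        slopes[i] = tc @ (hs - hs.mean()) / (tc @ tc)
    centers = np.arange(n) + window // 2
    return slopes, centers


def flux_from_trace(
    trace: CapillaryTrace, geom: DeviceGeometry, window: int = 11
) -> tuple[np.ndarray, np.ndarray]:
    """Volume rate (uL/h) filling the capillary, from rolling height slopes.

    Returns ``(times_s, flux_uL_per_h)`` aligned to window centres; the
    sign is positive for a rising column.  Slope (mm/s) times the
    capillary cross-section (mm^2) is mm^3/s = uL/s.
    """
    if window < 2 or window > len(trace):
        raise ConfigurationError(f"window must be in [2, {len(trace)}]")
    slopes, centers = _rolling_slopes(trace.t, trace.h, window)
    return trace.t[centers], slopes * geom.A_mc * 3600.0


def ppc_from_trace(
    trace: CapillaryTrace, geom: DeviceGeometry, window: int = 11
) -> PPCCurve:
    """Pump performance curve from one capillary filling trace.

    Each window centre contributes (dP, J): the head rho g h minus the
    capillary offset, signed per setup (S1: dP = +head, J = +filling
    rate; S2: dP = -head and the filling rate is basal-to-apical, so J
    is negated to keep J positive apical-to-basal).  Quantised heights
    produce tied dP values; ties are aggregated by averaging J so the
    returned curve has strictly increasing dP.
    """
    _, flux = flux_from_trace(trace, geom, window)
    centers = np.arange(len(trace) - window + 1) + window // 2
    head = pressure_from_height(trace.h[centers], trace.rho, offset=geom.capillary_offset)
    if trace.setup == "S1":
        dp, j = head, flux
    else:
        dp, j = -head, -flux
    order = np.argsort(dp, kind="stable")
    dp, j = dp[order], j[order]
    uniq, inverse = np.unique(dp, return_inverse=True)
    j_mean = np.bincount(inverse, weights=j) / np.bincount(inverse)
    return PPCCurve(delta_P=uniq, J=j_mean, unit_tag="per-device")


def shear_to_flow(tau: float, mu: float, width: float, height: float) -> float:
    """Channel flow rate (m^3/s) producing wall shear stress tau (Pa).

    Wide-slot (parallel-plate) approximation Q = tau w h^2 / (6 mu);
    adequate at the device's 8:1 channel aspect ratio.
    """
    if min(tau, mu, width, height) <= 0:
        raise ConfigurationError("tau, mu, width and height must all be > 0")
    return tau * width * height**2 / (6.0 * mu)


def flow_to_shear(Q: float, mu: float, width: float, height: float) -> float:
    """Wall shear stress (Pa) at channel flow rate Q (m^3/s); inverse of shear_to_flow."""
    if min(Q, mu, width, height) <= 0:
        raise ConfigurationError("Q, mu, width and height must all be > 0")
    return 6.0 * mu * Q / (width * height**2)


def device_resolution(geom: DeviceGeometry, rho: float = 1020.0) -> tuple[float, float]:
    """(volume resolution in uL, pressure resolution in Pa) of the readout.

    One ruler graduation resolves A_mc x ruler_resolution of volume and
    rho g x ruler_resolution of pressure (10 Pa per mm of culture
    medium).
    """
    volume_res = geom.A_mc * geom.ruler_resolution
    pressure_res = rho * STANDARD_GRAVITY * geom.ruler_resolution * 1e-3
    return volume_res, pressure_res
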