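"""Steady-state mechanistic model of active trans-epithelial fluid pumping.

The epithelium is modelled as a three-compartment serial engine:

    apical bath  ->  cell  ->  lateral cleft  ->  basal bath

Water crosses the apical and basolateral membranes down its combined
hydraulic/osmotic potential (Kedem-Katchalsky, reflection coefficient
``sigma_r``), and leaves the cleft through a purely hydraulic exit of
conductance ``K_s``.  The cell actively translocates an ideal neutral
solute: influx across the apical membrane and efflux across the
basolateral membrane at a common rate set by :class:`ActiveFluxSpec`.
This through-pumping enriches the lateral cleft, the resulting standing
osmotic gradient draws water across the epithelium, and the flux
declines with the imposed hydrostatic gradient dP = P_basal - P_apical
until a stall pressure dP* is reached -- the pump performance curve
(PPC) of the tissue.

At steady state the model satisfies

    J = L_a [(P_a - P_c) - RT sigma (c_a - c_c)]
      = L_b [(P_c - P_s) - RT sigma (c_c - c_s)]
      = K_s (P_s - P_b)

    g_a (c_a - c_c) + A_ap = g_b (c_c - c_s) + A_bl
    g_b (c_c - c_s) + A_bl = k_d (c_s - c_b) + J c_s

with J > 0 for apical-to-basal flow (the advective carrier switches to
the basal concentration when the flow reverses).  For a constant active flux A and
isotonic baths the stall pressure has the closed form

    dP* = RT sigma A / (k_d + g_a g_b / (g_a + g_b))

which serves as the analytic anchor for the numerical solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "ActiveFluxSpec",
    "BathConditions",
    "EpitheliumParams",
    "PumpState",
    "PPCCurve",
    "ConfigurationError",
    "SteadyStateError",
    "ModelRegimeError",
    "BracketingError",
    "active_flux",
    "steady_state",
    "ppc_curve",
    "stall_pressure",
    "stall_closed_form_isotonic",
    "zero_pressure_flux",
    "osmolarity_scan",
    "per_cell_force",
    "flux_to_device_rate",
]


class ConfigurationError(ValueError):
    """Invalid model configuration or contract violation."""


class SteadyStateError(RuntimeError):
    """Solver failed to reach the residual tolerance; carries residuals."""

    def __init__(self, message: str, residuals: dict[str, float] | None = None):
        super().__init__(message)
        self.residuals = residuals or {}


class ModelRegimeError(RuntimeError):
    """The converged state left the physical regime (negative concentration)."""


class BracketingError(RuntimeError):
    """Root bracketing failed; carries the diagnostic PPC endpoints."""

    def __init__(self, message: str, endpoints: dict[float, float] | None = None):
        super().__init__(message)
        self.endpoints = endpoints or {}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

Variant = Literal["constant", "osmotic_linear", "apical_pressure"]
Orientation = Literal["absorptive", "secretory"]


@dataclass(frozen=True)
class ActiveFluxSpec:
    """Specification of the active trans-cellular solute flux.

    variant
        ``constant``        -> A = A0
        ``osmotic_linear``  -> A = A0 [1 + alpha RT sigma (c_a - c_b) / Pi_ref]
        ``apical_pressure`` -> A = A0 max(0, 1 - P_a / P_sat)
    The result is clipped at zero in every variant.  ``apical_fraction``
    and ``basal_fraction`` scale the active term applied at each
    membrane; the default (1, 1) is a through-pump with equal apical
    influx and basolateral efflux.
    """

    variant: Variant = "constant"
    A0: float = 0.0                     # mol m^-2 s^-1
    alpha: float = 0.0                  # dimensionless (osmotic_linear)
    Pi_ref: float = 773100.0            # Pa (osmotic_linear normalisation)
    P_sat: float = 1000.0               # Pa (apical_pressure extinction)
    apical_fraction: float = 1.0
    basal_fraction: float = 1.0

    def __post_init__(self):
        if self.variant not in ("constant", "osmotic_linear", "apical_pressure"):
            raise ConfigurationError(f"unknown active-flux variant {self.variant!r}")
        if self.A0 < 0:
            raise ConfigurationError("A0 must be >= 0")
        if self.Pi_ref <= 0:
            raise ConfigurationError("Pi_ref must be > 0")
        if self.variant == "apical_pressure" and self.P_sat == 0:
            raise ConfigurationError("P_sat must be nonzero for the apical_pressure variant")


@dataclass(frozen=True)
class BathConditions:
    """Osmolarities (mol m^-3) and hydraulic pressures (Pa) of the two baths."""

    c_a: float = 300.0
    c_b: float = 300.0
    P_a: float = 0.0
    P_b: float = 0.0

    def __post_init__(self):
        if self.c_a < 0 or self.c_b < 0:
            raise ConfigurationError("bath osmolarities must be >= 0")


@dataclass(frozen=True)
class EpitheliumParams:
    """Membrane permeabilities, cleft drainage, geometry and active-flux spec.

    L_a, L_b : hydraulic conductivity of the apical / basolateral
        membrane (m Pa^-1 s^-1); K_s : hydraulic conductance of the
        cleft exit (m Pa^-1 s^-1); g_a, g_b : passive solute
        permeabilities (m s^-1); k_d : diffusive cleft drainage
        coefficient (m s^-1); sigma_r : reflection coefficient; RT : gas
        constant x temperature (J mol^-1, 2577 at 310 K); A_cell :
        single-cell footprint (m^2); A_epi : epithelium area exposed in
        the device (m^2).
    """

    L_a: float
    L_b: float
    K_s: float
    g_a: float
    g_b: float
    k_d: float
    sigma_r: float = 1.0
    RT: float = 2577.0
    active: ActiveFluxSpec = field(default_factory=ActiveFluxSpec)
    orientation: Orientation = "absorptive"
    A_cell: float = 4.0e-10
    A_epi: float = 1.2e-5

    def __post_init__(self):
        for name in ("L_a", "L_b", "K_s", "g_a", "g_b", "k_d"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.sigma_r <= 1.0:
            raise ConfigurationError("sigma_r must lie in [0, 1]")
        if self.RT <= 0:
            raise ConfigurationError("RT must be > 0")
        if self.A_cell <= 0 or self.A_epi <= 0:
            raise ConfigurationError("A_cell and A_epi must be > 0")
        if self.orientation not in ("absorptive", "secretory"):
            raise ConfigurationError(f"unknown orientation {self.orientation!r}")

    @property
    def L_series(self) -> float:
        """Series hydraulic conductance of the three water pathways."""
        return 1.0 / (1.0 / self.L_a + 1.0 / self.L_b + 1.0 / self.K_s)

    @property
    def orientation_sign(self) -> int:
        return 1 if self.orientation == "absorptive" else -1

    def default_setup(self) -> str:
        """Device configuration matched to the pumping direction."""
        return "S1" if self.orientation == "absorptive" else "S2"


@dataclass(frozen=True)
class PumpState:
    """Steady-state compartment variables and the trans-epithelial flux.

    c_c, c_s in mol m^-3; P_c, P_s in Pa; J in m s^-1 (positive
    apical-to-basal).
    """

    c_c: float
    P_c: float
    c_s: float
    P_s: float
    J: float


@dataclass(frozen=True)
class PPCCurve:
    """Paired (dP, J) observations; dP strictly increasing."""

    delta_P: np.ndarray
    J: np.ndarray
    unit_tag: str = "per-area"  # J in m/s ("per-area") or uL/h ("per-device")

    def __post_init__(self):
        dp = np.asarray(self.delta_P, dtype=float)
        j = np.asarray(self.J, dtype=float)
        if dp.shape != j.shape or dp.ndim != 1:
            raise ConfigurationError("delta_P and J must be 1-D arrays of equal length")
        if dp.size >= 2 and not np.all(np.diff(dp) > 0):
            raise ConfigurationError("delta_P values must be strictly increasing")
        object.__setattr__(self, "delta_P", dp)
        object.__setattr__(self, "J", j)

    def __len__(self) -> int:
        return self.delta_P.size

    def to_frame(self) -> pd.DataFrame:
        col = "J_m_per_s" if self.unit_tag == "per-area" else "J_uL_per_h"
        return pd.DataFrame({"delta_P_Pa": self.delta_P, col: self.J})


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def active_flux(
    spec: ActiveFluxSpec,
    baths: BathConditions,
    state_pressures: dict[str, float] | None = None,
    *,
    rt_sigma: float = 2577.0,
) -> float:
    """Magnitude of the active solute flux (mol m^-2 s^-1), clipped at 0.

    ``state_pressures`` may override the apical pressure seen by the
    ``apical_pressure`` variant (key ``"P_a"``); by default the apical
    bath pressure is used.
    """
    if spec.variant == "constant":
        a = spec.A0
    elif spec.variant == "osmotic_linear":
        a = spec.A0 * (1.0 + spec.alpha * rt_sigma * (baths.c_a - baths.c_b) / spec.Pi_ref)
    elif spec.variant == "apical_pressure":
        p_a = baths.P_a if state_pressures is None else state_pressures.get("P_a", baths.P_a)
        a = spec.A0 * max(0.0, 1.0 - p_a / spec.P_sat)
    else:  # pragma: no cover - guarded by ActiveFluxSpec
        raise ConfigurationError(f"unknown active-flux variant {spec.variant!r}")
    return max(0.0, a)


def _active_terms(params: EpitheliumParams, baths: BathConditions) -> tuple[float, float]:
    """Signed active solute terms (apical influx, basolateral efflux)."""
    a = active_flux(params.active, baths, rt_sigma=params.RT * params.sigma_r)
    s = params.orientation_sign
    return s * params.active.apical_fraction * a, s * params.active.basal_fraction * a


def _solute_concentrations(
    params: EpitheliumParams, baths: BathConditions, a_ap: float, a_bl: float, J: float
) -> tuple[float, float]:
    """Solve the (linear, given J) solute balances for (c_c, c_s).

    The advective term at the cleft exit is upwinded: outflowing water
    (J >= 0) carries the cleft concentration, inflowing water (J < 0)
    carries the basal-bath concentration.  This keeps the balance
    physical (and non-singular) under strong reverse flow.
    """
    g_a, g_b, k_d = params.g_a, params.g_b, params.k_d
    # cell:  (g_a+g_b) c_c - g_b c_s = g_a c_a + a_ap - a_bl
    # cleft: g_b c_c - (g_b+k_d+[J]) c_s = -a_bl - k_d c_b + [J c_b]
    m11, m12, r1 = g_a + g_b, -g_b, g_a * baths.c_a + a_ap - a_bl
    if J >= 0:
        m21, m22, r2 = g_b, -(g_b + k_d + J), -a_bl - k_d * baths.c_b
    else:
        m21, m22, r2 = g_b, -(g_b + k_d), -a_bl - k_d * baths.c_b + J * baths.c_b
    det = m11 * m22 - m12 * m21
    if det == 0.0:
        raise SteadyStateError("singular solute balance (advective washout equals drainage)")
    c_c = (r1 * m22 - m12 * r2) / det
    c_s = (m11 * r2 - r1 * m21) / det
    return c_c, c_s


def steady_state(
    params: EpitheliumParams,
    baths: BathConditions,
    *,
    tol: float = 1e-10,
) -> PumpState:
    """Solve the serial pump-leak model for its steady state.

    The solute balances are linear once the volume flux J is fixed, and
    summing the three water equations gives J back from the cleft
    osmolarity, so the full system reduces to one scalar equation in J
    solved by bracketed Brent iteration.  ``tol`` is the normalised
    residual tolerance checked on the returned state.

    Raises :class:`SteadyStateError` on non-convergence and
    :class:`ModelRegimeError` if a compartment concentration is negative
    at the solution.
    """
    rts = params.RT * params.sigma_r
    a_ap, a_bl = _active_terms(params, baths)
    L = params.L_series

    def mismatch(J: float) -> float:
        _, c_s = _solute_concentrations(params, baths, a_ap, a_bl, J)
        return L * ((baths.P_a - baths.P_b) + rts * (c_s - baths.c_a)) - J

    # expanding bracket around the passive estimate; mismatch is
    # monotone decreasing in J (advective washout), so the root is unique
    j0 = mismatch(0.0)
    if j0 == 0.0:
        J = 0.0
    else:
        scale = max(abs(j0), L * max(1.0, abs(baths.P_a - baths.P_b)))
        lo, hi = -scale, scale
        for _ in range(200):
            if mismatch(lo) > 0 > mismatch(hi):
                break
            if mismatch(lo) <= 0:
                lo *= 4.0
            if mismatch(hi) >= 0:
                hi *= 4.0
        else:
            raise SteadyStateError(
                "could not bracket the steady-state flux",
                {"mismatch_lo": mismatch(lo), "mismatch_hi": mismatch(hi)},
            )
        J = brentq(mismatch, lo, hi, xtol=1e-22, rtol=8.9e-16, maxiter=200)

    c_c, c_s = _solute_concentrations(params, baths, a_ap, a_bl, J)
    P_s = baths.P_b + (J / params.K_s if params.K_s > 0 else 0.0)
    P_c = P_s + (J / params.L_b if params.L_b > 0 else 0.0) + rts * (c_c - c_s)
    state = PumpState(c_c=c_c, P_c=P_c, c_s=c_s, P_s=P_s, J=J)

    res = residuals(params, baths, state)
    norm = math.sqrt(sum(v * v for v in res.values()))
    if norm > tol:
        raise SteadyStateError(f"steady state residual norm {norm:.3e} exceeds {tol:.1e}", res)
    if c_c < 0 or c_s < 0:
        raise ModelRegimeError(
            f"negative concentration at solution (c_c={c_c:.4g}, c_s={c_s:.4g})"
        )
    return state


def residuals(
    params: EpitheliumParams, baths: BathConditions, state: PumpState
) -> dict[str, float]:
    """Normalised steady-state residuals (water equality x2, solute x2)."""
    rts = params.RT * params.sigma_r
    a_ap, a_bl = _active_terms(params, baths)
    j_a = params.L_a * ((baths.P_a - state.P_c) - rts * (baths.c_a - state.c_c))
    j_b = params.L_b * ((state.P_c - state.P_s) - rts * (state.c_c - state.c_s))
    j_s = params.K_s * (state.P_s - baths.P_b)
    s_cell_in = params.g_a * (baths.c_a - state.c_c) + a_ap
    s_cell_out = params.g_b * (state.c_c - state.c_s) + a_bl
    carrier = state.c_s if state.J >= 0 else baths.c_b  # upwinded advection
    s_cleft_out = params.k_d * (state.c_s - baths.c_b) + state.J * carrier

    j_scale = max(abs(state.J), params.L_series * max(1.0, rts * max(baths.c_a, baths.c_b, 1.0)))
    s_scale = max(
        abs(a_ap), abs(a_bl),
        max(params.g_a, params.g_b, params.k_d) * max(baths.c_a, baths.c_b, 1.0),
        abs(state.J) * max(baths.c_a, baths.c_b, 1.0),
        1e-300,
    )
    return {
        "water_ab": (j_a - j_b) / j_scale,
        "water_bs": (j_b - j_s) / j_scale,
        "solute_cell": (s_cell_in - s_cell_out) / s_scale,
        "solute_cleft": (s_cell_out - s_cleft_out) / s_scale,
    }


def _offset_baths(baths: BathConditions, delta_P: float, setup: str) -> BathConditions:
    """Apply a pressure gradient dP = P_basal - P_apical per device setup.

    S1 varies the basal pressure at fixed apical pressure; S2 the
    reverse.  Both report dP with the same sign convention.
    """
    if setup == "S1":
        return replace(baths, P_b=baths.P_a + delta_P)
    if setup == "S2":
        return replace(baths, P_a=baths.P_b - delta_P)
    raise ConfigurationError(f"unknown setup {setup!r} (expected 'S1' or 'S2')")


def ppc_curve(
    params: EpitheliumParams,
    baths: BathConditions,
    delta_P_grid: Sequence[float],
    *,
    setup: str | None = None,
    normalize: bool = False,
) -> PPCCurve:
    """Model pump performance curve over a grid of pressure gradients.

    For each dP the bath pressures are offset per the device setup and
    the steady state solved.  With ``normalize=True`` all fluxes are
    divided by the maximum flux on the grid (the convention used to
    overlay osmolarity scans).
    """
    grid = np.asarray(list(delta_P_grid), dtype=float)
    if grid.size == 0:
        raise ConfigurationError("delta_P grid must be non-empty")
    if grid.size >= 2 and not np.all(np.diff(grid) > 0):
        raise ConfigurationError("delta_P grid must be strictly increasing")
    setup = setup or params.default_setup()
    fluxes = np.empty_like(grid)
    for i, dp in enumerate(grid):
        try:
            fluxes[i] = steady_state(params, _offset_baths(baths, dp, setup)).J
        except (SteadyStateError, ModelRegimeError) as exc:
            raise type(exc)(f"steady state failed at delta_P={dp:.6g} Pa: {exc}") from exc
    if normalize:
        fluxes = fluxes / np.max(fluxes)
    return PPCCurve(delta_P=grid, J=fluxes, unit_tag="per-area")


def zero_pressure_flux(
    params: EpitheliumParams, baths: BathConditions, *, setup: str | None = None
) -> float:
    """Flux J0 (m/s) at zero pressure gradient; device rate via A_epi."""
    setup = setup or params.default_setup()
    return steady_state(params, _offset_baths(baths, 0.0, setup)).J


def stall_pressure(
    params: EpitheliumParams,
    baths: BathConditions,
    *,
    setup: str | None = None,
    bracket: tuple[float, float] = (-2000.0, 2000.0),
    xtol: float = 1e-9,
) -> float:
    """Stall pressure dP* (Pa) with J(dP*) = 0, by bracketed root finding.

    The bracket is expanded geometrically (up to |dP| = 1e7 Pa) if the
    flux does not change sign on the initial interval; failing that a
    :class:`BracketingError` carries the endpoint fluxes.
    """
    setup = setup or params.default_setup()

    def flux(dp: float) -> float:
        return steady_state(params, _offset_baths(baths, dp, setup)).J

    lo, hi = float(bracket[0]), float(bracket[1])
    f_lo, f_hi = flux(lo), flux(hi)
    for _ in range(30):
        if f_lo == 0.0:
            return lo
        if f_hi == 0.0:
            return hi
        if f_lo * f_hi < 0:
            break
        lo, hi = lo * 2.0, hi * 2.0
        if max(abs(lo), abs(hi)) > 1e7:
            raise BracketingError(
                "no sign change of J on the bracket", {lo: flux(lo), hi: flux(hi)}
            )
        f_lo, f_hi = flux(lo), flux(hi)
    else:
        raise BracketingError("no sign change of J on the bracket", {lo: f_lo, hi: f_hi})
    return brentq(flux, lo, hi, xtol=xtol, rtol=1e-14, maxiter=200)


def stall_closed_form_isotonic(params: EpitheliumParams) -> float:
    """Analytic stall pressure for a constant active flux and isotonic baths.

    dP* = +- RT sigma A0 / (k_d + g_a g_b / (g_a + g_b)), positive for
    absorptive orientation.  Contract: constant variant with the default
    through-pump placement.
    """
    spec = params.active
    if spec.variant != "constant":
        raise ConfigurationError("closed form requires the constant active-flux variant")
    if spec.apical_fraction != 1.0 or spec.basal_fraction != 1.0:
        raise ConfigurationError("closed form requires the symmetric through-pump placement")
    G = params.g_a * params.g_b / (params.g_a + params.g_b)
    return params.orientation_sign * params.RT * params.sigma_r * spec.A0 / (params.k_d + G)


def osmolarity_scan(
    params: EpitheliumParams,
    baths: BathConditions,
    dilution_fractions: Iterable[float],
    *,
    setup: str | None = None,
) -> pd.DataFrame:
    """(J0, dP*) under fractional dilution of the upstream bath.

    For each fraction eps the apical osmolarity (basal for secretory
    orientations) is scaled by (1 - eps) and both pump descriptors are
    recomputed.  Returns columns ``fraction``, ``J0``, ``deltaP_star``.
    """
    rows = []
    for eps in dilution_fractions:
        if not 0.0 <= eps <= 0.9:
            raise ConfigurationError(f"dilution fraction {eps} outside [0, 0.9]")
        if params.orientation == "absorptive":
            diluted = replace(baths, c_a=baths.c_a * (1.0 - eps))
        else:
            diluted = replace(baths, c_b=baths.c_b * (1.0 - eps))
        rows.append(
            {
                "fraction": eps,
                "J0": zero_pressure_flux(params, diluted, setup=setup),
                "deltaP_star": stall_pressure(params, diluted, setup=setup),
            }
        )
    return pd.DataFrame(rows)


def per_cell_force(stall: float, A_cell: float) -> float:
    """Mechanical force per cell (N) developed at the stall pressure."""
    if A_cell <= 0:
        raise ConfigurationError("A_cell must be > 0")
    return stall * A_cell


def flux_to_device_rate(J: float, A_epi: float) -> float:
    """Convert a per-area flux (m/s) to a device volume rate (uL/h)."""
    return J * A_epi * 3.6e12  # m^3/s -> uL/h
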