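"""Ground-truth synthetic inputs for every stage of the pipeline.

Three generators mirror the raw data the analysis consumes:

* capillary filling traces, by integrating the device-coupled column
  ODE dh/dt = J(dP(h)) A_epi / A_mc against the mechanistic pump model,
  then sampling, adding Gaussian reading noise and quantising to the
  ruler graduation -- the saturating rise-to-stall curves of a pumping
  monolayer;
* PPC point sets sampled directly from a linear pump line
  J = J0 (1 - dP/dP*), for estimator calibration;
* qPCR CT tables with programmed per-gene fold changes against a
  housekeeping gene.

All randomness flows from explicit integer seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import pump_model as pm
from .device_hydraulics import STANDARD_GRAVITY, CapillaryTrace, DeviceGeometry
from .expression_stats import DEFAULT_HOUSEKEEPING, QpcrTable
from .pump_model import BathConditions, ConfigurationError, EpitheliumParams, PPCCurve

__all__ = [
    "SyntheticConfig",
    "simulate_capillary_trace",
    "generate_ppc_points",
    "generate_qpcr_table",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Sampling and noise model of the videography readout.

    noise_sd_mm : Gaussian reading noise on the column height;
    quantize_mm : ruler graduation the reading is rounded to;
    frame_interval_s / duration_s : sampling grid; h0_mm : initial
    column height; seed : required integer seed.
    """

    seed: int
    noise_sd_mm: float = 0.2
    quantize_mm: float = 1.0
    frame_interval_s: float = 60.0
    duration_s: float = 36000.0
    h0_mm: float = 0.0

    def __post_init__(self):
        if self.noise_sd_mm < 0:
            raise ConfigurationError("noise_sd_mm must be >= 0")
        if self.quantize_mm < 0:
            raise ConfigurationError("quantize_mm must be >= 0")
        if self.frame_interval_s <= 0 or self.duration_s <= 0:
            raise ConfigurationError("frame_interval_s and duration_s must be > 0")


def simulate_capillary_trace(
    params: EpitheliumParams,
    geom: DeviceGeometry,
    baths: BathConditions,
    cfg: SyntheticConfig,
    *,
    setup: str | None = None,
    rho: float = 1020.0,
) -> CapillaryTrace:
    """Simulate one microcapillary filling trace from the pump model.

    The column height obeys dh/dt = s J(dP(h)) A_epi / A_mc with
    dP(h) = s (rho g h - capillary_offset) and s = +1 for S1 (basal
    column) or -1 for S2 (apical column): an absorptive monolayer fills
    the basal capillary until the head reaches its stall pressure.  The
    exact solution is sampled at the frame interval, Gaussian noise is
    added and the readings are quantised to the ruler graduation.
    """
    setup = setup or params.default_setup()
    if setup not in ("S1", "S2"):
        raise ConfigurationError(f"unknown setup {setup!r}")
    s = 1.0 if setup == "S1" else -1.0
    gain = (geom.A_epi / geom.A_mc) * 1e3  # J (m/s) -> dh/dt (mm/s)

    def rhs(_t, h):
        head = rho * STANDARD_GRAVITY * h[0] * 1e-3 - geom.capillary_offset
        dp = s * head
        state = pm.steady_state(params, pm._offset_baths(baths, dp, setup))
        return [s * state.J * gain]

    t_eval = np.arange(0.0, cfg.duration_s + cfg.frame_interval_s / 2, cfg.frame_interval_s)
    sol = solve_ivp(
        rhs, (0.0, float(t_eval[-1])), [cfg.h0_mm],
        t_eval=t_eval, method="RK45", rtol=1e-8, atol=1e-10,
    )
    if not sol.success:
        raise RuntimeError(f"capillary ODE integration failed: {sol.message}; state={sol.y[:, -1]}")
    h_true = sol.y[0]

    rng = np.random.default_rng(cfg.seed)
    h = h_true + rng.normal(0.0, cfg.noise_sd_mm, size=h_true.shape)
    if cfg.quantize_mm > 0:
        h = np.round(h / cfg.quantize_mm) * cfg.quantize_mm
    return CapillaryTrace(
        t=sol.t, h=h, setup=setup, rho=rho,
        metadata={"seed": cfg.seed, "noise_sd_mm": cfg.noise_sd_mm,
                  "quantize_mm": cfg.quantize_mm, "h_true_final_mm": float(h_true[-1])},
    )


def generate_ppc_points(
    J0: float, deltaP_star: float, n: int, noise_frac: float, seed: int
) -> PPCCurve:
    """Noisy points on the pump line J = J0 (1 - dP/dP*).

    n evenly spaced dP values span [0, 1.2 dP*] (descending for
    secretory curves with negative stall), with Gaussian noise of SD
    ``noise_frac * |J0|`` added to J.  Seeded and reproducible.
    """
    if n < 3:
        raise ConfigurationError("n must be >= 3")
    if deltaP_star == 0:
        raise ConfigurationError("deltaP_star must be nonzero")
    dp = np.sort(np.linspace(0.0, 1.2 * deltaP_star, n))
    j = J0 * (1.0 - dp / deltaP_star)
    rng = np.random.default_rng(seed)
    j = j + rng.normal(0.0, noise_frac * abs(J0), size=n)
    return PPCCurve(delta_P=dp, J=j, unit_tag="per-device")


def generate_qpcr_table(
    genes: list[str],
    n_samples: int,
    baseline_ct: dict[str, float],
    fold_changes: dict[str, float],
    noise_sd_ct: float,
    seed: int,
    *,
    housekeeping: str = DEFAULT_HOUSEKEEPING,
) -> QpcrTable:
    """CT table with two groups and programmed fold changes.

    Control samples read CT = baseline; treated samples read
    CT = baseline - log2(fold_change), so the dCT method recovers the
    programmed fold change exactly at zero noise.  The housekeeping
    gene must be listed and keeps fold change 1.
    """
    if housekeeping not in genes:
        raise ConfigurationError(f"housekeeping gene {housekeeping!r} must be in genes")
    rng = np.random.default_rng(seed)
    cols, groups, data = [], {}, []
    for gene in genes:
        base = baseline_ct[gene]
        fc = 1.0 if gene == housekeeping else fold_changes.get(gene, 1.0)
        row = np.concatenate([
            base + rng.normal(0.0, noise_sd_ct, n_samples),
            base - np.log2(fc) + rng.normal(0.0, noise_sd_ct, n_samples),
        ])
        data.append(row)
    for i in range(n_samples):
        cols.append(f"control_{i + 1}")
        groups[f"control_{i + 1}"] = "control"
    for i in range(n_samples):
        cols.append(f"treated_{i + 1}")
        groups[f"treated_{i + 1}"] = "treated"
    ct = pd.DataFrame(np.vstack(data), index=genes, columns=cols)
    return QpcrTable(ct=ct, housekeeping=housekeeping, sample_groups=groups)
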