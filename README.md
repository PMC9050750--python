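# epipump

Mechanistic modelling and analysis of **active trans-epithelial fluid
pumping** — for researchers studying how kidney (and other transporting)
epithelia move water against hydrostatic pressure gradients, and how that
pumping fails or reverses in cystic disease.

Transporting epithelia behave like mechanical fluid pumps: the
trans-epithelial volume flux *J* is maximal at zero pressure gradient
(*J*₀) and declines roughly linearly with the opposing gradient
ΔP = P_basal − P_apical until a **stall pressure** ΔP\* is reached. The
(ΔP, *J*) relation is the epithelium's **pump performance curve (PPC)**.
Normal absorptive kidney epithelia stall at ΔP\* ≈ 100–250 Pa pumping
apical→basal; cystic (ADPKD) epithelia pump in reverse and sustain
ΔP\* ≈ −300 Pa. At 300–400 µm² per cell, such stalls correspond to
30–100 nN of mechanical force per cell.

The package provides:

* **`pump_model`** — a three-compartment serial pump-leak engine
  (apical bath → cell → lateral intercellular cleft → basal bath).
  Water crosses each membrane by Kedem–Katchalsky fluxes
  *J* = L_p[ΔP − σRTΔc]; an active trans-cellular solute flux *A*
  (apical influx, basolateral efflux) enriches the cleft, and the
  standing osmotic gradient drives water. For a constant active flux and
  isotonic baths the stall has the closed form
  **ΔP\* = RTσ·A / (k_d + g_a g_b/(g_a+g_b))**, used as the analytic
  anchor of the numerical solver. Osmolarity-dependent and
  apical-pressure-dependent active-flux variants reproduce the two
  observed PPC behaviours (osmolarity-shifting vs osmolarity-insensitive
  stall).
* **`device_hydraulics`** — microfluidic-device mathematics: column
  height → pressure (ρgh − capillary offset), rolling-window height
  slope × capillary cross-section → flux, trace → PPC, wall shear stress
  ↔ channel flow, and readout resolutions (0.31 µL, 10 Pa at a 1 mm
  ruler graduation).
* **`ppc_estimation`** — OLS and isotonic fits for (*J*₀, ΔP\*),
  case-resampling bootstrap CIs, and exact Mann–Whitney group
  comparison.
* **`dome_pressure`** — Young–Laplace dome pressure from micro-needle
  meniscus curvature (2γ/R) and dome wall tension (PR/2).
* **`synthetic_data`** — generators for device-coupled capillary filling
  traces (ODE against the pump model, with reading noise and ruler
  quantisation), linear PPC point sets, and qPCR CT tables.
* **`expression_stats`** — ΔCT relative quantification against a
  housekeeping gene (18S rRNA) and population-SD Z-score matrices.
* **`cli_io` / `epipump` CLI** — config parsing, trace/PPC CSV dialects,
  and an end-to-end `simulate → trace-to-ppc → fit` pipeline.

## Worked example

Simulate a 10 h filling trace of the packaged reference absorptive
epithelium (60 s frames, 0.2 mm reading noise, 1 mm ruler quantisation)
and recover its pump descriptors:

```python
from epipump.cli_io import load_config, run_pipeline

bundle = run_pipeline(load_config("demo_pipeline"))
print(bundle["estimate"])
print(bundle["model_truth"])
```

prints (abridged):

```
{'J0_uL_per_h': 1.0949697370530558, 'deltaP_star_Pa': 200.873262701948,
 'slope': -0.005451047702041617, 'n_points': 14, 'method': 'linear',
 'extrapolated': True,
 'ci_J0': [1.0619632385818543, 1.1209999758815297],
 'ci_deltaP_star': [196.69555418498663, 205.25340356280006]}
{'deltaP_star_Pa': 200.0117690499867, 'J0_uL_per_h': 1.0872367640625311}
```

The estimated zero-pressure flux (1.09 µL/h over the 12 mm² window) and
stall pressure (201 Pa) recover the generating model's truth (1.087 µL/h,
200.0 Pa) to within 1%; `extrapolated: True` records that the 10 h run
stalled before the column actually crossed ΔP\*, so the zero crossing is
an extrapolation of the fitted line. The same steps are available from
the shell:

```sh
epipump simulate --params mdck_normal --seed 11 --out trace.csv
epipump trace-to-ppc --trace trace.csv --window 101 --out ppc.csv
epipump fit --ppc ppc.csv --bootstrap 500
```

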