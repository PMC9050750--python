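# Reference absorptive epithelium ("mdck_normal").
# Calibrated so the isotonic stall pressure is ~200 Pa and the device-level
# zero-pressure flux is ~1 uL/h over the 12 mm^2 exposed area.
epithelium:
  L_a: 1.5e-9        # m Pa^-1 s^-1
  L_b: 1.5e-9
  K_s: 1.5e-9
  g_a: 2.6e-4        # m s^-1
  g_b: 2.6e-4
  k_d: 2.0e-9        # m s^-1 (weak diffusive cleft drainage)
  sigma_r: 1.0
  RT: 2577.0         # J mol^-1 at 310 K
  orientation: absorptive
  A_cell: 4.0e-10    # m^2 (400 um^2 footprint)
  A_epi: 1.2e-5      # m^2 (6 mm x 2 mm)
  active:
    variant: constant
    A0: 1.009e-5     # mol m^-2 s^-1
baths:
  c_a: 300.0         # mol m^-3
  c_b: 300.0
  P_a: 0.0           # Pa gauge
  P_b: 0.0
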