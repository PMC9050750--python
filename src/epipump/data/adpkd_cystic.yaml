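# Reference secretory (cystic) epithelium ("adpkd_cystic").
# Same passive parameters as the absorptive reference; the active solute
# through-pump runs basal-to-apical and is calibrated so the isotonic stall
# pressure is ~ -300 Pa.
epithelium:
  L_a: 1.5e-9
  L_b: 1.5e-9
  K_s: 1.5e-9
  g_a: 2.6e-4
  g_b: 2.6e-4
  k_d: 2.0e-9
  sigma_r: 1.0
  RT: 2577.0
  orientation: secretory
  A_cell: 4.0e-10
  A_epi: 1.2e-5
  active:
    variant: constant
    A0: 1.5134e-5
baths:
  c_a: 300.0
  c_b: 300.0
  P_a: 0.0
  P_b: 0.0
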