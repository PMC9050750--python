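# Demo end-to-end pipeline config: simulate a 10 h absorptive filling trace
# (60 s frames, 0.2 mm reading noise, 1 mm ruler quantisation) and recover
# (J0, stall) from it.  The 101-sample (~1.7 h) estimation window suits
# hour-scale stall runs quantised at 1 mm.
epithelium:
  L_a: 1.5e-9
  L_b: 1.5e-9
  K_s: 1.5e-9
  g_a: 2.6e-4
  g_b: 2.6e-4
  k_d: 2.0e-9
  sigma_r: 1.0
  RT: 2577.0
  orientation: absorptive
  A_cell: 4.0e-10
  A_epi: 1.2e-5
  active:
    variant: constant
    A0: 1.009e-5
baths:
  c_a: 300.0
  c_b: 300.0
  P_a: 0.0
  P_b: 0.0
geometry:
  A_mc: 0.31
  ruler_resolution: 1.0
  capillary_offset: 0.0
  A_epi: 12.0
  channel_width: 2.0
  channel_height: 0.25
synthesis:
  seed: 11
  noise_sd_mm: 0.2
  quantize_mm: 1.0
  frame_interval_s: 60.0
  duration_s: 36000.0
  h0_mm: 0.0
estimation:
  method: linear
  window: 101
  bootstrap: 500
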