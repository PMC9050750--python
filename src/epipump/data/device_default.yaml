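# Default device geometry: 0.31 mm^2 microcapillary read against a 1 mm
# ruler (0.31 uL / 10 Pa resolution), 6 mm x 2 mm x 250 um apical channel.
geometry:
  A_mc: 0.31
  ruler_resolution: 1.0
  capillary_offset: 0.0
  A_epi: 12.0
  channel_width: 2.0
  channel_height: 0.25
rho: 1020.0
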