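# PEEP/FiO2 co-titration grids (cmH2O PEEP allowed at each FiO2 level),
# reproducing the public ARDSNet lower- and higher-PEEP tables.  The engine
# looks up the nearest-not-above FiO2 level and accepts any PEEP within
# `peep_tolerance` of an allowed value at that level.
low_peep:
  0.30: [5]
  0.40: [5, 8]
  0.50: [8, 10]
  0.60: [10]
  0.70: [10, 12, 14]
  0.80: [14]
  0.90: [14, 16, 18]
  1.00: [18, 20, 22, 24]
high_peep:
  0.30: [5, 8, 10, 12, 14]
  0.40: [14, 16]
  0.50: [16, 18, 20]
  0.60: [20]
  0.70: [20]
  0.80: [20, 22]
  0.90: [22]
  1.00: [22, 24]
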