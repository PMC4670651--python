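# Cross-linking sweep over the physiological three-level grids:
# association constant Ka (naive -> affinity-matured antibodies),
# initial aggregate concentration (30 ug interferon-beta dose -> 40 mg mAb
# dose), and an antigen-specific B-cell fraction ladder up to the 1% upper
# bound.  Middle levels are the (rounded) geometric means of the extremes.
kind: crosslink
sweep:
  n: 100
  k_on: 8.64e-3        # pM^-1 day^-1
  decay_base: 0.5
  ka_levels: [1.0e-7, 1.0e-5, 1.0e-3]      # pM^-1
  aga0_levels: [0.1, 12.0, 1500.0]         # pM
  fraction_levels: [1.0e-6, 1.0e-5, 6.0e-5, 1.0e-4, 1.0e-3, 1.0e-2]
  s_values: [2, 5, 10]
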