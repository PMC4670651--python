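# Low-affinity baseline (epitopes Kd 1230 and 850 nM, uM-range) versus two
# aggregate mimics: a 16.6-fold internalization-rate increase, and the
# induction of one additional high-affinity epitope (Kd 38 nM).
kind: ada
reference: low-affinity
scenarios:
  - name: low-affinity
    subcellular:
      epitopes: [{kd_mhc_nM: 1230.0}, {kd_mhc_nM: 850.0}]
  - name: low-affinity-ir-x16.6
    subcellular:
      internalization_rate: 239.04
      epitopes: [{kd_mhc_nM: 1230.0}, {kd_mhc_nM: 850.0}]
  - name: plus-high-affinity
    subcellular:
      epitopes: [{kd_mhc_nM: 1230.0}, {kd_mhc_nM: 850.0}, {kd_mhc_nM: 38.0}]
shared:
  regimen: {dose_mg: 40.0, interval_days: 14.0, n_doses: 6}
  subcellular: {internalization_rate: 14.4, degradation_rate: 17.28}
  cellular: {danger_signal_ng: 350.0}
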