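# The three epitope-affinity conditions crossed with biweekly doses of
# 40, 4, 0.4 and 0.04 mg (12 scenarios).  Each dose level references the
# low-affinity baseline at the same dose.
kind: ada
dose_ladder_mg: [40.0, 4.0, 0.4, 0.04]
reference_condition: low-affinity
conditions:
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
  regimen: {interval_days: 14.0, n_doses: 6}
  subcellular: {internalization_rate: 14.4, degradation_rate: 17.28}
  cellular: {danger_signal_ng: 350.0}
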