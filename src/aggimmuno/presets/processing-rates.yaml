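# Aggregate-enhanced antigen processing with high-affinity epitopes already
# present: baseline (IR0 = 14.4/day, DR0 = 17.28/day) versus a 16.6-fold
# increase of either the internalization or the degradation rate.
kind: ada
reference: baseline
scenarios:
  - name: baseline
    subcellular: {internalization_rate: 14.4, degradation_rate: 17.28}
  - name: ir-x16.6
    subcellular: {internalization_rate: 239.04, degradation_rate: 17.28}
  - name: dr-x16.6
    subcellular: {internalization_rate: 14.4, degradation_rate: 286.848}
shared:
  regimen: {dose_mg: 40.0, interval_days: 14.0, n_doses: 6}
  subcellular:
    epitopes: [{kd_mhc_nM: 123.0}, {kd_mhc_nM: 85.0}]
  cellular: {danger_signal_ng: 350.0}
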