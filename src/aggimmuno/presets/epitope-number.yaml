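# Effect of aggregate-induced additional epitopes when two high-affinity
# epitopes (Kd 123 and 85 nM) are already presented.  The Kd values of the
# synthetic third and fourth epitopes (500 and 1000 nM) are stand-ins
# chosen inside the uM-to-nM window of MHC class II epitopes.
kind: ada
reference: two-epitopes
scenarios:
  - name: two-epitopes
    subcellular:
      epitopes: [{kd_mhc_nM: 123.0}, {kd_mhc_nM: 85.0}]
  - name: three-epitopes
    subcellular:
      epitopes: [{kd_mhc_nM: 123.0}, {kd_mhc_nM: 85.0}, {kd_mhc_nM: 500.0}]
  - name: four-epitopes
    subcellular:
      epitopes: [{kd_mhc_nM: 123.0}, {kd_mhc_nM: 85.0}, {kd_mhc_nM: 500.0},
                 {kd_mhc_nM: 1000.0}]
shared:
  regimen: {dose_mg: 40.0, interval_days: 14.0, n_doses: 6}
  cellular: {danger_signal_ng: 350.0}
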