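# ADA response across danger-signal (LPS-equivalent) amounts.  350 ng is
# the baseline calibration for a nonaggregated mAb; 1750 ng is the 5-fold
# aggregate-enhanced level.  The sub-baseline rungs {175, 70, 35, 7} ng are
# a synthetic descending ladder standing in for unreported low-danger
# conditions.  Dose: 40 mg biweekly; epitopes: the two high-affinity
# predicted mAb epitopes (Kd 123 and 85 nM).
kind: ada
reference: ds-350
scenarios:
  - name: ds-1750
    cellular: {danger_signal_ng: 1750.0}
  - name: ds-350
    cellular: {danger_signal_ng: 350.0}
  - name: ds-175
    cellular: {danger_signal_ng: 175.0}
  - name: ds-70
    cellular: {danger_signal_ng: 70.0}
  - name: ds-35
    cellular: {danger_signal_ng: 35.0}
  - name: ds-7
    cellular: {danger_signal_ng: 7.0}
shared:
  regimen: {dose_mg: 40.0, interval_days: 14.0, n_doses: 6}
  subcellular:
    internalization_rate: 14.4
    degradation_rate: 17.28
    epitopes: [{kd_mhc_nM: 123.0}, {kd_mhc_nM: 85.0}]
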