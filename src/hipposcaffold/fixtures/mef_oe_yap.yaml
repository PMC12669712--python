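# YAP hnRNA in KSR1-overexpressing vs wild-type MEFs: 18.8-fold increase
# relative to the WT calibrator, GAPDH reference.
genes: [YAP, GAPDH]
reference_gene: GAPDH
conditions: [WT, KSR1_OE]
calibrator_condition: WT
true_fold_change:
  YAP: {WT: 1.0, KSR1_OE: 18.8}
  GAPDH: {WT: 1.0, KSR1_OE: 1.0}
reference_ct_mean: 18.0
replicates: 3
ct_noise_sd: 0.15
runs: 3
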