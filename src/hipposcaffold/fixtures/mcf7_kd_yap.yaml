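# YAP hnRNA in KSR1-knockdown vs control-siRNA MCF-7 cells: 51% reduction
# (fold change 0.49 vs the siCtrl calibrator), GAPDH reference.
genes: [YAP, GAPDH]
reference_gene: GAPDH
conditions: [siCtrl, siKSR1]
calibrator_condition: siCtrl
true_fold_change:
  YAP: {siCtrl: 1.0, siKSR1: 0.49}
  GAPDH: {siCtrl: 1.0, siKSR1: 1.0}
reference_ct_mean: 18.0
replicates: 3
ct_noise_sd: 0.15
runs: 3
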