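# CTGF hnRNA in KSR1-knockout vs wild-type MEFs: 93% reduction
# (fold change 0.07 vs the WT calibrator), GAPDH reference.
genes: [CTGF, GAPDH]
reference_gene: GAPDH
conditions: [WT, KSR1_KO]
calibrator_condition: WT
true_fold_change:
  CTGF: {WT: 1.0, KSR1_KO: 0.07}
  GAPDH: {WT: 1.0, KSR1_KO: 1.0}
reference_ct_mean: 18.0
replicates: 3
ct_noise_sd: 0.15
runs: 3
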