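# KSR1-null MEF effect profile: nuclear target-protein signal reduced by 38%
# relative to wt (yap_nuclear_mean 62 vs 100), modest cytoplasmic retention,
# and fewer/shorter actin stress fibers (reduced RhoA/actin signaling).
condition_name: ksr1_null
cells_per_image: 10
nucleus_radius_mean: 11.0
nucleus_radius_sd: 1.5
nucleus_axis_ratio_mean: 0.75
nucleus_displacement_frac_mean: 0.15
cell_radius_mean: 26.0
cell_radius_sd: 3.0
yap_nuclear_mean: 62.0
yap_cyto_mean: 46.0
fiber_count_mean: 3.0
fiber_length_mean: 22.0
fiber_length_sd: 5.0
background_level: 5.0
noise_sd: 4.0
dna_level: 200.0
actin_level: 60.0
fiber_level: 140.0
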