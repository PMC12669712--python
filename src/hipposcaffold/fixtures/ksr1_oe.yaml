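# KSR1-overexpressing MEF effect profile: elevated total and nuclear target
# protein and a denser stress-fiber network than wt.
condition_name: ksr1_oe
cells_per_image: 10
nucleus_radius_mean: 11.0
nucleus_radius_sd: 1.5
nucleus_axis_ratio_mean: 0.75
nucleus_displacement_frac_mean: 0.15
cell_radius_mean: 26.0
cell_radius_sd: 3.0
yap_nuclear_mean: 150.0
yap_cyto_mean: 80.0
fiber_count_mean: 8.0
fiber_length_mean: 34.0
fiber_length_sd: 6.0
background_level: 5.0
noise_sd: 4.0
dna_level: 200.0
actin_level: 60.0
fiber_level: 140.0
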