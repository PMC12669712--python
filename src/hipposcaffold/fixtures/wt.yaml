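# Wild-type MEF effect profile. Intensities are arbitrary units; condition
# effects are encoded as ratios of channel means between profiles.
condition_name: wt
cells_per_image: 10
nucleus_radius_mean: 11.0
nucleus_radius_sd: 1.5
nucleus_axis_ratio_mean: 0.75
nucleus_displacement_frac_mean: 0.15
cell_radius_mean: 26.0
cell_radius_sd: 3.0
yap_nuclear_mean: 100.0
yap_cyto_mean: 40.0
fiber_count_mean: 6.0
fiber_length_mean: 30.0
fiber_length_sd: 6.0
background_level: 5.0
noise_sd: 4.0
dna_level: 200.0
actin_level: 60.0
fiber_level: 140.0
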