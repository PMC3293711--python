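array_efficiency_sd: 0.3
array_offset_sd: 0.3
array_scale_sd: 0.1
background_mean: 10.0
background_sd: 1.0
channel_gain_sd: 0.1
dye_trend_coeffs:
- 0.0
- 0.08
- 0.04
enriched_fraction: 0.35
enrichment_shift: 1.2
mean_fragment_length: 500.0
n_arrays: 8
n_control_probes: 4000
n_planted_sites: 20
n_promoter_probes: 30000
n_tiling_probes: 6000
noise_sd: 0.3
partial_enrichment: 1.0
probe_length: 50
probe_spacing: 100
red_background_log2: 8.5
seed: 0
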