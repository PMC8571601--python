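# Demo end-to-end run on a synthetic world (completes in ~1 minute).
# All analysis defaults mirror the workflow's standard choices: 1 km
# thinning, target-group background, LQHPT features with RM 1.5, cloglog
# output, MTSS + 0.8 thresholds, 7 Jenks classes for dispersal limits.

[run]
seed = 5
outdir = "scratch/demo_run"

[world]
rows = 64
cols = 80
n_occurrences = 250
bias_strength = 1.5
n_target_species = 6
n_per_species = 100

[occurrence_prep]
thin_km = 1.0
thin_repeats = 5
n_background = 3000
kernel_sigma_cells = 5.0

[model]
features = "LQHPT"
rm = 1.5
optimal_threshold = 0.8

[scenarios.2050_rcp26]
delta_t = 1.0
precip_scale = 0.97

[scenarios.2050_rcp85]
delta_t = 2.0
precip_scale = 0.92

[scenarios.2070_rcp26]
delta_t = 1.5
precip_scale = 0.95

[scenarios.2070_rcp85]
delta_t = 3.5
precip_scale = 0.85

[dispersal]
n_classes = 7
suitability_top_cost = 1000.0

# Landscape cost rules: value range -> traversal cost. The species cannot
# cross the highest ridges (upper elevation limit).
[dispersal.cost_rules]
elevation = [[0.0, 1400.0, 1.0], [1400.0, 100000.0, 1000000.0]]

[output]
raster_format = "ascii_grid"
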