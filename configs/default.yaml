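# Default pipeline configuration (every key optional; these mirror the
# built-in defaults).  Pass to any CLI subcommand with --config.

scene:
  image_height: 1024
  image_width: 1024
  n_cells: 10
  blebbing_fraction: 0.5
  cell_radius_mean: 55.0
  cell_radius_sd: 6.0
  nucleus_radius_fraction: 0.55
  n_blebs_range: [8, 14]
  bleb_amplitude_fraction: 0.15
  n_fas_range: [6, 12]
  fa_area_range: [60.0, 150.0]
  touching_pair_fraction: 0.0
  noise_sd: 25.0
  poisson_noise: false

segmentation:
  smooth_sigma: 2.0
  dim_fraction: 0.20        # background = dimmest 20% of pixels
  threshold_factor: 2.0     # threshold = factor x mean(dimmest fraction)
  reseg_factor: 1.5         # higher threshold for re-splitting
  border_policy: drop
  nuclei_preset: nuclei

morphometry:
  savgol_window: 9
  savgol_polyorder: 3
  curvature_step: 8

thresholds:
  curvature_min: 0.029      # px^-1
  intensity_ratio_max: 1.15 # nuclear / cytoplasmic adhesion marker
  area_ratio_max: 4.5       # cell / nucleus area
  nucleus_area_min: 1000    # px, outlier filter
  cell_area_max: 150000     # px, outlier filter

fa:
  fa_preset: fa
  min_fa_area: 30           # px
  upper_percentile: 99      # pooled over the whole dataset
  lower_count_max: 4        # cells with <= 4 adhesions removed

pst:
  nuclei:
    lpf_sigma: 0.05
    phase_strength: 0.5
    warp_strength: 12.0
    phase_threshold_low: 0.02
    min_region_area: 200
    morphology_ops: [[close, 3], [fill_holes, 0], [open, 3]]
  fa:
    lpf_sigma: 0.25
    phase_strength: 0.5
    warp_strength: 12.0
    phase_threshold_low: 0.02
    min_region_area: 10
    morphology_ops: [[close, 1], [fill_holes, 0]]
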