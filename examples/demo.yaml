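# Demo study: 6+6 synthetic samples on a 600x200 grid, all four
# feature-extraction methods.  Run with:
#   gcims run --config examples/demo.yaml --out demo_out
# Any key omitted here falls back to the built-in demo defaults.

seed: 0

simulate:
  n_per_class: [6, 6]
  n_retention: 600
  n_drift: 200
  peak_catalog_size: 30
  marker_count: 15
  marker_effect: 2.0
  noise_sd: 15.0
  drift_scale_jitter: 0.02
  retention_warp_amplitude: 8.0

preprocess:
  # Savitzky-Golay [window, degree]; chosen for the simulator's peak
  # widths by the 1% apex-loss rule (instrument-scale data typically
  # use 19/2 and 27/2)
  sg_drift: [5, 2]
  sg_retention: [9, 2]
  # Psalsa parameters are intensity-scale dependent
  psalsa_drift: {lam: 1.0e+5, p: 5.0e-3, k: 50.0}
  psalsa_retention: {lam: 1.0e+8, p: 5.0e-3, k: 50.0}
  rip_retention_window: [0.0, 20.0]   # quiet zone, seconds
  tic_drift_window: [7.2, 15.0]       # analyte region, ms
  cow_segment: 25
  cow_slack: 10
  cow_overlap: 5
  optimize_cow: false

features:
  methods: [ric_area, ric, full_matrix, peak_table]
  rip_window: [6.0, 6.8]              # drift ms window containing the RIP
  peaks:
    exclude_drift_below_ms: 7.2
    mode: per_sample

model:
  calibration_fraction: 0.66
  max_lv: 6
  n_boot: 50
  n_perm: 0
  reselect_lv: false
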