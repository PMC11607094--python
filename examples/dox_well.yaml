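# Well-perfused synthetic tumor, doxorubicin + cyclophosphamide regimen.
# Numeric defaults mirror the study conditions: a 0.25-day time step with
# mechanics re-solved every 4 steps (daily), influence threshold 0.1 on the
# total-effects index, 1000 bootstrap resamples for confidence intervals.
scenario:
  perfusion: well
  shape: [16, 16, 16]
  spacing_mm: [2.0, 2.0, 2.0]
  tumor_radius_mm: 8.0           # fits with a healthy-tissue margin
  peak_density_fraction: 0.6     # initial peak N0 / theta
  smooth_mm: 2.0
  noise_amplitude: 0.02
  seed: 1
regimen: dox_cyc                 # four 2-week cycles, T = 56 days
solver:
  dt: 0.25                       # days
  mech_every: 4                  # quasistatic mechanics solved daily
sa:
  n_samples: 128                 # rows per Latin-hypercube matrix
  seed: 42
  eps_s: 0.1                     # S_T threshold for influence
  n_boot: 1000
out_dir: runs
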