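# Synthetic cohort pipeline configuration (all keys optional; unknown keys
# are rejected).  Run with:  lungmap all --config examples/cohort.yaml --out run/
seed: 1
cohort:
  n_controls: 6
  n_vapers: 14
  hr_post_increase: 3.2     # bpm, mean heart-rate rise after exposure
  bmi_dq_slope: -0.06       # mL/min/mL per kg/m2, BMI-dependent dQ
phantom:
  shape: 64                 # grid side (dual-echo acquisition matrix)
  snr: 40.0
  enhancement: 0.12         # fractional signal rise at 100% O2
analysis:
  sv_grid_n: 50
  min_corr: 0.5
  vessel_threshold: 0.35    # fraction of max delivered blood
  coil_smoothing: 5.0       # voxels
write_images: false         # true -> per-subject NIfTI maps
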