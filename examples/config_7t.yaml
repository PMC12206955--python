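# Default 7 T cohort: seven hearts, SNR 50, per-heart anatomical and
# tissue-parameter variation. `sanmap run --config examples/config_7t.yaml`
field: 7T
n_hearts: 7
sigma: 0.02
seed: 0
param_jitter: true
geometry:
  shape: [64, 64]
  spacing_mm: 0.234375
  margin_mm: 1.2
  epi_thickness_mm: 0.7
  san_center_mm: [3.8, 7.5]
  san_thickness_mm: 2.5
  san_length_mm: 12.0
  san_tilt_deg: 0.0
  jitter: true
segmentation:
  n_bins: 256
  san_fraction: 0.20
  histology_spacing_um: 46.875
  histology_target_um: 200.0
stats:
  t_variant: welch
  reference_contrast: RAFF2
  per_sample_contrast: true
output_dir: sanmap_out
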