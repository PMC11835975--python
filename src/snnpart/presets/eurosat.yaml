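# EuroSAT preset: 64x64x3 -> 484 (3x3x3 receptive fields, stride 3) -> 128 -> 10.
# The first hidden layer fits in one run via label-addressed sparse blocks but
# is split into 8 parts to reduce per-run input event bandwidth, giving 10
# runs in total.  The dataset itself is not bundled; this preset documents the
# topology, encoder and training setup for an optional full-scale run.
name: eurosat
input:
  shape: [64, 64, 3]
layers:
  - {name: hidden1, size: 484, fan_in: 27, connectivity: receptive_field,
     kernel: [3, 3, 3], stride: 3, parts: 8}
  - {name: hidden2, size: 128, fan_in: 484}
  - {name: readout, size: 10, fan_in: 128}
encoder:
  scheme: lif_current
  T: 64.0
  dt: 0.5
  x_min_bias: 0.2
  tau_en: 8.0
  theta_en: 1.0
  sigma_in: 0.01
augmentation:
  random_flips: true
train:
  hidden_sizes: [484, 128]
  epochs: 500
  lr: 1.0e-3
  lr_schedule: halving
  halve_at: [10, 20, 30, 40, 50, 60]
  patience: 25
  decoding: last_value
  T: 64.0
  dt: 0.5
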