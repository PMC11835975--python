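# Full-resolution MNIST preset: 784 -> 256 LIF -> 10 LI, linear TTFS encoding.
# The dataset itself is not bundled; this preset documents the topology,
# encoder and training setup for an optional full-scale run.
name: mnist
input:
  shape: [28, 28, 1]
layers:
  - {name: hidden, size: 256, fan_in: 784}
  - {name: readout, size: 10, fan_in: 256}
encoder:
  scheme: linear
  T: 30.0
  dt: 0.5
  x_min: 0.0
  x_max: 1.0
augmentation:
  rotate_degrees: 25
  rotate_prob: 0.5
  normalize: true
train:
  hidden_sizes: [256]
  epochs: 100
  dropout_p: 0.15
  lr: 1.0e-3
  lr_schedule: exponential
  lr_decay: 0.97
  decoding: max_over_time
  rate_w: 1.0e-3
  sat_w: 1.0e-3
  weight_w: 1.0e-3
  T: 30.0
  dt: 0.5
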