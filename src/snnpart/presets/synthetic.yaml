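# Built-in synthetic 3-class blob task: trains in seconds without downloads.
name: synthetic
input:
  shape: [8, 8]
layers:
  - {name: hidden, size: 24, fan_in: 64}
  - {name: readout, size: 3, fan_in: 24}
encoder:
  scheme: linear
  T: 30.0
  dt: 0.5
neurons:
  v_th: 0.5
train:
  hidden_sizes: [24]
  lr: 5.0e-3
  epochs: 50
  batch_size: 32
  beta: 5.0
  init_scale: 2.0
  rate_w: 1.0e-4
  sat_w: 1.0e-3
  weight_w: 1.0e-3
  sat_bound: 2.0
  weight_bound: 2.0
  T: 30.0
  dt: 0.5
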