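schema_version: 1

model:
  depth: 5
  base_channels: 8
  n_classes: 5
  input_shape: [128, 64]
  variant: proposed

train:
  loss_weights: [1.0, 0.0, 1.0]
  initial_lr: 0.001
  batch_size: 4
  lr_factor: 0.1
  lr_patience: 5
  early_stop_patience: 10
  checkpoint_interval: 100
  max_epochs: 30
  k_folds: 6
  seed: 0
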