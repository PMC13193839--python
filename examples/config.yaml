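# Desk-scale phantom run for `lungct train` / `lungct ablate`.
phantom:
  enabled: true
  n_per_class: 60
split:
  test_per_class: 15
  seed: 0
augment: null           # desk-scale runs train without augmentation
model:
  backbone: tiny_cnn
  feature_dim: 64
  gru_units: [16, 8]
  dense_units: [32, 16]
train:
  learning_rate: 0.001
  batch_size: 16
  max_epochs: 30
  patience: 5
  freeze_policy: none   # no pretrained backbone to protect at desk scale
  seed: 0
seed: 0
out_dir: scratch/run
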