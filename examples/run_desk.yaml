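# Desk-scale end-to-end run: simulate -> networks -> CNN -> Grad-CAM -> metrics
# morphnet-asd run --config examples/run_desk.yaml
seed: 1
out_dir: morphnet_run
simulation:
  grid: 48
  n_regions: 116
  n_asd: 30
  n_tc: 30
  shift_magnitude: 1.0
network:
  grid_size: 128
model:
  learning_rate: 1.0e-3
  max_epochs: 12
  early_stop_patience: 4
cv:
  n_folds: 5
  n_repeats: 2
evaluation:
  baselines: [RF, SVM, XGB, AE]
  n_perm: 99
  flip_fraction: 0.2
  ae_hidden: [128, 16]
  ae_epochs: 10
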