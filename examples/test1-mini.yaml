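# Desk-scale ischemic-slab run: FOM snapshots for 9 scar locations,
# DL-ROM (n = 3) and equal-dimension POD-Galerkin baseline, evaluated on
# the 4 held-out locations.  ~5 minutes on one CPU:
#
#   cardiorom compare --config examples/test1-mini.yaml --out runs/mini
scenario: test1-mini
seed: 1
dlrom:
  n: 3
  conv_channels: [4, 8, 16]
  kernel: 5
  dfnn_hidden: [50, 50, 50, 50]
  lr: 1.0e-3
  batch_size: 40
  max_epochs: 150
  patience: 150
pod:
  n_modes: 3
  deim_modes: 60
evaluate: true
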