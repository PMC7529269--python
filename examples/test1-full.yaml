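# Full-scale ischemic slab (64x64, 49 training / 36 testing scar
# locations, 1000 snapshots per run).  Snapshot generation takes ~10 min;
# training the DL-ROM at this scale takes hours on one CPU.
scenario: test1
seed: 1
dlrom:
  n: 3
  conv_channels: [8, 16, 32, 64]
  kernel: 5
  dfnn_hidden: [50, 50, 50, 50]
  lr: 1.0e-4
  batch_size: 40
  max_epochs: 10000
  patience: 500
pod:
  eps_pod: 1.0e-3
  n_clusters: 6
evaluate: true
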