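name: resnet21
family: resnet1d
input_channels: 6
input_frames: 50
head: global_avg_pool_dense
head_hidden: []
n_classes: 2
dropout: 0.0
blocks:
- kind: convolutional_block
  filters:
  - 16
  - 16
  - 64
  kernel: 3
  stride: 2
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: convolutional_block
  filters:
  - 16
  - 16
  - 64
  kernel: 3
  stride: 2
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: convolutional_block
  filters:
  - 16
  - 16
  - 64
  kernel: 3
  stride: 2
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: identity_block
  filters:
  - 16
  - 16
  - 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: convolutional_block
  filters:
  - 16
  - 16
  - 64
  kernel: 3
  stride: 2
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: identity_block
  filters:
  - 16
  - 16
  - 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: convolutional_block
  filters:
  - 16
  - 16
  - 64
  kernel: 3
  stride: 2
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
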