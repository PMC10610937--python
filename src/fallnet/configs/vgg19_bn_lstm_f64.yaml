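name: vgg19_bn_lstm_f64
family: vgg1d
input_channels: 6
input_frames: 50
head: lstm_dense
head_hidden: []
n_classes: 2
dropout: 0.0
blocks:
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: max_pool
  filters: 1
  kernel: 1
  stride: 1
  with_bn: false
  pool_size: 2
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: max_pool
  filters: 1
  kernel: 1
  stride: 1
  with_bn: false
  pool_size: 2
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: max_pool
  filters: 1
  kernel: 1
  stride: 1
  with_bn: false
  pool_size: 2
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: max_pool
  filters: 1
  kernel: 1
  stride: 1
  with_bn: false
  pool_size: 2
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 64
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: max_pool
  filters: 1
  kernel: 1
  stride: 1
  with_bn: false
  pool_size: 2
  dropout: 0.0
  slim: false
- kind: lstm_unit
  filters: 64
  kernel: 1
  stride: 1
  with_bn: false
  pool_size: null
  dropout: 0.5
  slim: false
- kind: lstm_unit
  filters: 64
  kernel: 1
  stride: 1
  with_bn: false
  pool_size: null
  dropout: 0.5
  slim: false
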