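name: vgg16_bn
family: vgg1d
input_channels: 6
input_frames: 50
head: flatten_dense
head_hidden:
- 4096
- 4096
n_classes: 2
dropout: 0.5
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
  filters: 128
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 128
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
  filters: 256
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 256
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 256
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
  filters: 512
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 512
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 512
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
  filters: 512
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 512
  kernel: 3
  stride: 1
  with_bn: true
  pool_size: null
  dropout: 0.0
  slim: false
- kind: vgg_block
  filters: 512
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
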