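"""Walk the architecture zoo: from the conv+LSTM benchmark to tinyfallnet.

Parameter counts come from layer closed forms; the float32 memory figure is
a lower bound on any saved-model file.  The lightweighting ladder removes
identity blocks (shape-preserving residual blocks) one at a time, then drops
the entry block's 1x1 reduce conv.
"""

from fallnet import count_parameters, estimate_memory_mb, get_model_spec, list_models
from fallnet.zoo import count_conv_layers, propagate_shapes

print(f"{'variant':24s} {'params':>10s} {'MiB':>7s}")
for name in list_models():
    spec = get_model_spec(name)
    est = estimate_memory_mb(spec)
    print(f"{name:24s} {est.trainable_parameters:>10,d} {est.megabytes:>7.3f}")

print("\nlightweighting ladder (identity-block removal, deepest stage first):")
for name in ("resnet24", "resnet21", "resnet18", "resnet15", "tinyfallnet"):
    spec = get_model_spec(name)
    print(f"  {name:12s} {count_conv_layers(spec):2d} conv layers, "
          f"{count_parameters(spec):>6,d} params")

spec = get_model_spec("tinyfallnet")
print("\ntinyfallnet shape flow for a 50-frame x 6-channel window:")
length, channels = spec.input_frames, spec.input_channels
for block, (l, c) in zip(spec.blocks, propagate_shapes(spec)):
    print(f"  {block.kind:20s} ({length:2d}, {channels:2d}) -> ({l:2d}, {c:2d})")
    length, channels = l, c
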