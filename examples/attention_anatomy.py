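"""Anatomy of one grouped-cascade-attention layer.

Runs a single GCA layer on a random feature map and prints the bookkeeping
that defines it: the channel slices each head receives, the window grid, and
the parameter saving of channel-split heads over full-width heads.  The
printed ratio equals the head count: feeding each head a 1/h channel slice
cuts the q/k/v projection cost by exactly h.
"""

import numpy as np

from gcanet import AttentionConfig, GroupedCascadeAttention, split_heads, window_partition

cfg = AttentionConfig(dim=32, num_heads=4, key_dim=8, window_size=7)
layer = GroupedCascadeAttention(cfg, np.random.default_rng(0))
layer.eval()

x = np.random.default_rng(1).normal(size=(1, 32, 14, 14))
slices = split_heads(x, cfg.num_heads)
print(f"input {x.shape[1]} channels -> {len(slices)} head slices of "
      f"{slices[0].shape[1]} channels")

windows, grid = window_partition(x, cfg.window_size)
print(f"spatial {grid.height}x{grid.width} -> {grid.num_windows} windows of "
      f"{cfg.window_size}x{cfg.window_size} ({grid.rows} rows x {grid.cols} cols)")

y = layer(x)
print(f"layer output shape {y.shape} (equals input shape)")

split_qkv = sum(p.conv.weight.size
                for projs in (layer.q_proj, layer.k_proj, layer.v_proj)
                for p in projs)
full_qkv = cfg.num_heads * (cfg.dim * cfg.key_dim * 2 + cfg.dim * cfg.value_dim)
print(f"q/k/v weights: {split_qkv} (channel-split) vs {full_qkv} (full-width) "
      f"-> saving factor {full_qkv // split_qkv}")
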