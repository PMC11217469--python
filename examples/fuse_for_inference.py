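"""Structural reparameterization of the multi-branch CNN blocks.

Each EC block trains with three parallel branches (3x3 group conv, 1x1 group
conv, identity), but with frozen normalization statistics the sum of the
branches is itself one 3x3 group convolution.  This script fuses a tiny
model and prints the largest logit discrepancy on fixed inputs — at float64
precision it is ~1e-14, i.e. the fusion is exact up to rounding — along
with the parameter counts before and after.
"""

import numpy as np

from gcanet import build_model, count_parameters, tiny_config
from gcanet.ec import ECBlock

model = build_model(tiny_config(num_classes=2))
model.train()
model(np.random.default_rng(0).normal(size=(8, 3, 64, 64)))  # realistic BN stats
model.eval()

x = np.random.default_rng(1).uniform(size=(4, 3, 64, 64))
before_logits = model(x)
before_params = count_parameters(model)

model.fuse_()
after_logits = model(x)
fused_params = sum(
    b.fused_conv.weight.size + b.fused_conv.bias.size
    for b in model.modules() if isinstance(b, ECBlock)
)

print(f"max |fused - multibranch| logit gap: {np.abs(after_logits - before_logits).max():.2e}")
print(f"trainable params {before_params:,}; fused EC conv params {fused_params:,}")
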