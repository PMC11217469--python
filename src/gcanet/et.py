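"""Sandwich-layout efficient-Transformer (ET) block.

One grouped-cascade-attention layer sandwiched between two stacks of N
(patch-embedding + feed-forward) pairs:

    T_out = [PE -> FFN] x N ( attn ( [PE -> FFN] x N (T_in) ) )

The patch embedding is a residual 3x3 group convolution injecting local
inductive bias before each FFN; the FFN is two pointwise convolutions with an
expansion ratio, acting per spatial position.  Every sublayer — patch embed,
FFN and attention — is residual, so the block is the identity map when all
learnable weights are zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .gca import AttentionConfig, GroupedCascadeAttention
from .nn import ConfigurationError, ShapeError


@dataclass
class ETBlockConfig:
    dim: int
    n_ffn: int = 2          # N: (patch-embed + FFN) pairs per side of attention
    ffn_ratio: int = 3      # hidden-width multiplier of the FFN
    pe_groups: int = 8      # group count of the 3x3 patch-embedding conv
    attention: AttentionConfig | None = None

    def __post_init__(self) -> None:
        if self.n_ffn < 1:
            raise ConfigurationError(f"n_ffn must be >= 1, got {self.n_ffn}")
        if self.ffn_ratio < 1:
            raise ConfigurationError(f"ffn_ratio must be >= 1, got {self.ffn_ratio}")
        if self.dim % self.pe_groups:
            raise ConfigurationError(
                f"pe_groups={self.pe_groups} must divide dim={self.dim}"
            )
        if self.attention is None:
            self.attention = AttentionConfig(dim=self.dim)
        if self.attention.dim != self.dim:
            raise ConfigurationError(
                f"attention.dim={self.attention.dim} != block dim={self.dim}"
            )


class LocalPatchEmbed(nn.Module):
    """Residual local-mixing layer: ``x + gconv3x3(x)`` (shape preserved)."""

    def __init__(self, dim: int, groups: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.conv = nn.ConvBN(dim, dim, 3, padding=1, groups=groups, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.conv(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.conv.backward(dy)


class FFN(nn.Module):
    """Residual per-position MLP: ``x + conv1x1(dim->r*dim) -> ReLU -> conv1x1(->dim)``."""

    def __init__(self, dim: int, ratio: int, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.hidden = ratio * dim
        self.fc1 = nn.ConvBN(dim, self.hidden, 1, rng=rng)
        self.act = nn.ReLU()
        self.fc2 = nn.ConvBN(self.hidden, dim, 1, rng=rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return x + self.fc2(self.act(self.fc1(x)))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy + self.fc1.backward(self.act.backward(self.fc2.backward(dy)))


class ETBlock(nn.Module):
    """N x (patch embed, FFN), one residual GCA layer, N x (patch embed, FFN)."""

    def __init__(self, cfg: ETBlockConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        mk_pair = lambda: (LocalPatchEmbed(cfg.dim, cfg.pe_groups, rng), FFN(cfg.dim, cfg.ffn_ratio, rng))
        self.pre = nn.ModuleList()
        self.post = nn.ModuleList()
        for _ in range(cfg.n_ffn):
            pe, ffn = mk_pair()
            self.pre.extend([pe, ffn])
        self.attn = GroupedCascadeAttention(cfg.attention, rng)
        for _ in range(cfg.n_ffn):
            pe, ffn = mk_pair()
            self.post.extend([pe, ffn])

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.cfg.dim:
            raise ShapeError(f"expected {self.cfg.dim} channels, got {x.shape[1]}")
        for layer in self.pre:
            x = layer(x)
        x = x + self.attn(x)
        for layer in self.post:
            x = layer(x)
        return x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        for layer in reversed(self.post):
            dy = layer.backward(dy)
        dy = dy + self.attn.backward(dy)
        for layer in reversed(self.pre):
            dy = layer.backward(dy)
        return dy
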