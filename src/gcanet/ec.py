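"""Multi-branch efficient-CNN (EC) block.

Two variants of a RepVGG-style multi-branch convolutional unit built from a
3x3 *group* convolution branch and a 1x1 convolution branch (plus an identity
branch when the block neither downsamples nor changes width).  Each branch
carries its own batch normalization; branch outputs are summed and passed
through ReLU.  With frozen statistics the whole block collapses exactly into
a single 3x3 group convolution (:func:`fuse_ec_block`), trading the richer
training-time topology for a plain inference-time operator.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import ConfigurationError, ShapeError


@dataclass
class ECBlockConfig:
    in_channels: int
    out_channels: int
    stride: int = 1
    groups: int = 4
    has_identity: bool | None = None  # None -> inferred

    def __post_init__(self) -> None:
        if self.stride not in (1, 2):
            raise ConfigurationError(f"stride must be 1 or 2, got {self.stride}")
        if self.in_channels % self.groups or self.out_channels % self.groups:
            raise ConfigurationError(
                f"groups={self.groups} must divide in_channels={self.in_channels} "
                f"and out_channels={self.out_channels}"
            )
        can_identity = self.stride == 1 and self.in_channels == self.out_channels
        if self.has_identity is None:
            self.has_identity = can_identity
        elif self.has_identity and not can_identity:
            raise ConfigurationError(
                "identity branch requires stride 1 and in_channels == out_channels"
            )


class ECBlock(nn.Module):
    """out = ReLU( gconv3x3(x) + conv1x1(x) [+ BN(x)] ), each branch normalized."""

    def __init__(self, cfg: ECBlockConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.branch3 = nn.ConvBN(cfg.in_channels, cfg.out_channels, 3,
                                 stride=cfg.stride, padding=1, groups=cfg.groups, rng=rng)
        # the 1x1 branch shares the group count so the block folds exactly
        # into one 3x3 group conv (RepVGG grouped-variant convention)
        self.branch1 = nn.ConvBN(cfg.in_channels, cfg.out_channels, 1,
                                 stride=cfg.stride, padding=0, groups=cfg.groups, rng=rng)
        if cfg.has_identity:
            self.branch_id = nn.BatchNorm2d(cfg.out_channels)
        self.relu = nn.ReLU()
        # populated by fuse_(): inference-only single-conv path
        self.fused_conv: nn.Conv2d | None = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.cfg.in_channels:
            raise ShapeError(
                f"expected {self.cfg.in_channels} channels, got {x.shape[1]}"
            )
        if self.fused_conv is not None and not self.training:
            return self.relu(self.fused_conv(x))
        s = self.branch3(x) + self.branch1(x)
        if self.cfg.has_identity:
            s = s + self.branch_id(x)
        return self.relu(s)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        ds = self.relu.backward(dy)
        dx = self.branch3.backward(ds) + self.branch1.backward(ds)
        if self.cfg.has_identity:
            dx = dx + self.branch_id.backward(ds)
        return dx

    def fuse_(self) -> None:
        """Replace the multi-branch computation by its single-conv equivalent."""
        w, b = fuse_ec_block(self, self.cfg)
        conv = nn.Conv2d(self.cfg.in_channels, self.cfg.out_channels, 3,
                         stride=self.cfg.stride, padding=1,
                         groups=self.cfg.groups, bias=True)
        conv.weight.data = w
        conv.bias.data = b
        conv.eval()
        self.fused_conv = conv


def _pad_1x1_to_3x3(w: np.ndarray) -> np.ndarray:
    out = np.zeros(w.shape[:2] + (3, 3))
    out[:, :, 1, 1] = w[:, :, 0, 0]
    return out


def identity_kernel(channels: int, groups: int) -> np.ndarray:
    """3x3 group-conv kernel acting as the identity map.

    Channel ``c`` receives a unit tap at the center of its own position within
    its group, zero elsewhere.
    """
    cig = channels // groups
    w = np.zeros((channels, cig, 3, 3))
    for c in range(channels):
        w[c, c % cig, 1, 1] = 1.0
    return w


def fuse_ec_block(block: ECBlock, cfg: ECBlockConfig) -> tuple[np.ndarray, np.ndarray]:
    """Fold an EC block's branches into one 3x3 group conv (weight, bias).

    Each branch's batch normalization is folded into its convolution weights;
    the 1x1 branch is zero-padded to a 3x3 kernel; the identity branch becomes
    a per-group center-tap delta kernel scaled by its normalization.  The sum
    of the folded branches reproduces the pre-ReLU multi-branch output exactly
    (up to floating-point rounding).  Requires frozen statistics (eval mode).
    """
    if block.training:
        raise RuntimeError("branch fusion requires frozen statistics (eval mode)")
    g = cfg.groups
    w3, b3 = block.branch3.fused_weight_bias()
    w1, b1 = block.branch1.fused_weight_bias()
    weight = w3 + _pad_1x1_to_3x3(w1)
    bias = b3 + b1
    if cfg.has_identity:
        scale, shift = block.branch_id.fold()
        weight = weight + identity_kernel(cfg.out_channels, g) * scale[:, None, None, None]
        bias = bias + shift
    return weight, bias
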