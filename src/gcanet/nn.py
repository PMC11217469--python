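"""Minimal neural-network layer engine on numpy arrays.

Implements the handful of layer types the backbone needs — grouped 2-D
convolution, batch normalization, ReLU, a fully connected layer and global
average pooling — each with an explicit ``forward``/``backward`` pair so the
network can be trained without an external autodiff framework.  Feature maps
are ``float64`` arrays of shape ``(batch, channels, height, width)``.

Layers cache their forward activations only while in training mode, so
inference over large inputs stays memory-light.  A module-level MAC counter
can be armed to make every multiply–accumulate-bearing layer report its cost
as data flows through (normalization and activations are excluded by the
usual convention).
"""

from __future__ import annotations

import numpy as np


class ConfigurationError(ValueError):
    """An architecture hyperparameter combination is invalid."""


class ShapeError(ValueError):
    """An array does not have the shape an operation requires."""


# ---------------------------------------------------------------------------
# MAC accounting hook


class MacCounter:
    """Accumulates multiply–accumulate counts while armed via ``with``."""

    def __init__(self) -> None:
        self.total = 0

    def add(self, n: int) -> None:
        self.total += int(n)

    def __enter__(self) -> "MacCounter":
        global _ACTIVE_COUNTER
        self._prev = _ACTIVE_COUNTER
        _ACTIVE_COUNTER = self
        return self

    def __exit__(self, *exc) -> None:
        global _ACTIVE_COUNTER
        _ACTIVE_COUNTER = self._prev


_ACTIVE_COUNTER: MacCounter | None = None


def record_macs(n: int) -> None:
    if _ACTIVE_COUNTER is not None:
        _ACTIVE_COUNTER.add(n)


# ---------------------------------------------------------------------------
# Parameters and modules


class Parameter:
    """A learnable array with an accumulated gradient.

    ``decay`` marks whether the optimizer's (decoupled) weight decay applies;
    convention is to decay convolution/linear weights but not biases or
    normalization affine terms.
    """

    def __init__(self, data: np.ndarray, decay: bool = True) -> None:
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = np.zeros_like(self.data)
        self.decay = decay

    @property
    def size(self) -> int:
        return self.data.size


class Module:
    """Base class: parameter/buffer discovery, mode switching, state dicts."""

    def __init__(self) -> None:
        self.training = True

    # -- traversal ---------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Parameter):
                yield prefix + name, value
            elif isinstance(value, Module):
                yield from value.named_parameters(prefix + name + ".")
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield from sub.named_parameters(f"{prefix}{name}.{i}.")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def named_buffers(self, prefix: str = ""):
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield from value.named_buffers(prefix + name + ".")
            elif isinstance(value, ModuleList):
                for i, sub in enumerate(value):
                    yield from sub.named_buffers(f"{prefix}{name}.{i}.")
            else:
                for bname in getattr(self, "_buffers", ()):
                    if bname == name:
                        yield prefix + name, value

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, ModuleList):
                for sub in value:
                    yield from sub.modules()

    # -- modes -------------------------------------------------------------
    def train(self) -> "Module":
        for m in self.modules():
            m.training = True
        return self

    def eval(self) -> "Module":
        for m in self.modules():
            m.training = False
        return self

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data for name, p in self.named_parameters()}
        for name, b in self.named_buffers():
            state[name] = b
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        bufs = {name: None for name, _ in self.named_buffers()}
        for name, p in own.items():
            if name not in state:
                raise KeyError(f"missing parameter {name!r} in state")
            if p.data.shape != state[name].shape:
                raise ShapeError(
                    f"parameter {name!r}: expected shape {p.data.shape}, "
                    f"checkpoint has {state[name].shape}"
                )
            p.data = np.array(state[name], dtype=np.float64)
            p.grad = np.zeros_like(p.data)
        for name in bufs:
            if name in state:
                self._set_buffer(name, np.array(state[name], dtype=np.float64))

    def _set_buffer(self, dotted: str, value: np.ndarray) -> None:
        parts = dotted.split(".")
        obj = self
        for part in parts[:-1]:
            obj = obj[int(part)] if part.isdigit() else getattr(obj, part)
        setattr(obj, parts[-1], value)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)


class ModuleList(list):
    """A plain list of modules that participates in traversal."""


# ---------------------------------------------------------------------------
# Initialization


def he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)


# ---------------------------------------------------------------------------
# Layers


class Conv2d(Module):
    """Grouped 2-D convolution (im2col forward, col2im backward).

    Weight shape is ``(out_channels, in_channels // groups, k, k)``; the
    input/output channels are partitioned into ``groups`` independent groups,
    cutting parameters and MACs by the group count.
    """

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        groups: int = 1,
        bias: bool = False,
        rng: np.random.Generator | None = None,
    ) -> None:
        super().__init__()
        if in_channels % groups or out_channels % groups:
            raise ConfigurationError(
                f"groups={groups} must divide in_channels={in_channels} "
                f"and out_channels={out_channels}"
            )
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        rng = rng or np.random.default_rng(0)
        fan_in = (in_channels // groups) * kernel_size * kernel_size
        self.weight = Parameter(
            he_init(rng, (out_channels, in_channels // groups, kernel_size, kernel_size), fan_in)
        )
        self.bias = Parameter(np.zeros(out_channels), decay=False) if bias else None
        self._cache = None

    def out_spatial(self, h: int, w: int) -> tuple[int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        return (h + 2 * p - k) // s + 1, (w + 2 * p - k) // s + 1

    def _im2col(self, x: np.ndarray) -> tuple[np.ndarray, int, int]:
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            x = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)))
        b, c, hp, wp = x.shape
        ho, wo = (hp - k) // s + 1, (wp - k) // s + 1
        win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
        win = win[:, :, ::s, ::s]  # (b, c, ho, wo, k, k)
        return win, ho, wo

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_channels:
            raise ShapeError(
                f"expected {self.in_channels} input channels, got {x.shape[1]}"
            )
        b = x.shape[0]
        g = self.groups
        cig = self.in_channels // g
        cog = self.out_channels // g
        k = self.kernel_size
        col, ho, wo = self._im2col(x)
        # (b, g, cig, ho, wo, k, k) -> (g, b*ho*wo, cig*k*k)
        col = col.reshape(b, g, cig, ho, wo, k, k)
        cols = col.transpose(1, 0, 3, 4, 2, 5, 6).reshape(g, b * ho * wo, cig * k * k)
        w2 = self.weight.data.reshape(g, cog, cig * k * k)
        out = cols @ w2.transpose(0, 2, 1)  # (g, b*ho*wo, cog)
        out = out.reshape(g, b, ho, wo, cog).transpose(1, 0, 4, 2, 3)
        out = out.reshape(b, self.out_channels, ho, wo)
        if self.bias is not None:
            out += self.bias.data[None, :, None, None]
        record_macs(b * ho * wo * self.out_channels * cig * k * k)
        if self.training:
            self._cache = (cols, x.shape, ho, wo)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, x_shape, ho, wo = self._cache
        b = x_shape[0]
        g = self.groups
        cig = self.in_channels // g
        cog = self.out_channels // g
        k, s, p = self.kernel_size, self.stride, self.padding
        dy2 = dy.reshape(b, g, cog, ho, wo).transpose(1, 0, 3, 4, 2)
        dy2 = dy2.reshape(g, b * ho * wo, cog)
        w2 = self.weight.data.reshape(g, cog, cig * k * k)
        dw = dy2.transpose(0, 2, 1) @ cols  # (g, cog, cig*k*k)
        self.weight.grad += dw.reshape(self.weight.data.shape)
        if self.bias is not None:
            self.bias.grad += dy.sum(axis=(0, 2, 3))
        dcol = dy2 @ w2  # (g, b*ho*wo, cig*k*k)
        dcol = dcol.reshape(g, b, ho, wo, cig, k, k).transpose(1, 0, 4, 2, 3, 5, 6)
        dcol = dcol.reshape(b, self.in_channels, ho, wo, k, k)
        hp, wp = x_shape[2] + 2 * p, x_shape[3] + 2 * p
        dxp = np.zeros((b, self.in_channels, hp, wp))
        for u in range(k):
            for v in range(k):
                dxp[:, :, u : u + s * ho : s, v : v + s * wo : s] += dcol[:, :, :, :, u, v]
        if p:
            dxp = dxp[:, :, p:-p, p:-p]
        self._cache = None
        return dxp


class BatchNorm2d(Module):
    """Per-channel batch normalization with affine terms and running stats."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        super().__init__()
        self.channels = channels
        self.momentum = momentum
        self.eps = eps
        self.gamma = Parameter(np.ones(channels), decay=False)
        self.beta = Parameter(np.zeros(channels), decay=False)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self._buffers = ("running_mean", "running_var")
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.channels:
            raise ShapeError(f"expected {self.channels} channels, got {x.shape[1]}")
        if self.training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            n = x.shape[0] * x.shape[2] * x.shape[3]
            unbiased = var * n / max(n - 1, 1)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * unbiased
        else:
            mean, var = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * invstd[None, :, None, None]
        out = self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]
        if self.training:
            self._cache = (xhat, invstd)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, invstd = self._cache
        n = dy.shape[0] * dy.shape[2] * dy.shape[3]
        self.gamma.grad += (dy * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += dy.sum(axis=(0, 2, 3))
        g = self.gamma.data[None, :, None, None]
        dxhat = dy * g
        mean_dxhat = dxhat.mean(axis=(0, 2, 3), keepdims=True)
        mean_dxhat_xhat = (dxhat * xhat).mean(axis=(0, 2, 3), keepdims=True)
        dx = invstd[None, :, None, None] * (dxhat - mean_dxhat - xhat * mean_dxhat_xhat)
        self._cache = None
        return dx

    def fold(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (scale, shift) per channel for inference-time folding."""
        scale = self.gamma.data / np.sqrt(self.running_var + self.eps)
        shift = self.beta.data - self.running_mean * scale
        return scale, shift


class ReLU(Module):
    def __init__(self) -> None:
        super().__init__()
        self._mask = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        out = np.maximum(x, 0.0)
        if self.training:
            self._mask = x > 0
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        bound = 1.0 / np.sqrt(in_features)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Parameter(rng.uniform(-bound, bound, (out_features, in_features)))
        self.bias = Parameter(np.zeros(out_features), decay=False)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if x.shape[1] != self.in_features:
            raise ShapeError(f"expected {self.in_features} features, got {x.shape[1]}")
        record_macs(x.shape[0] * self.in_features * self.out_features)
        if self.training:
            self._cache = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._cache
        self.weight.grad += dy.T @ x
        self.bias.grad += dy.sum(axis=0)
        self._cache = None
        return dy @ self.weight.data


class GlobalAvgPool(Module):
    """(b, c, h, w) -> (b, c) spatial mean."""

    def __init__(self) -> None:
        super().__init__()
        self._shape = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        if self.training:
            self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        b, c, h, w = self._shape
        self._shape = None
        return np.broadcast_to(dy[:, :, None, None], (b, c, h, w)) / (h * w)


class ConvBN(Module):
    """Convolution followed by batch normalization (the network's basic unit)."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, groups: int = 1,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, stride,
                           padding, groups, bias=False, rng=rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.bn(self.conv(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.bn.backward(dy))

    def fused_weight_bias(self) -> tuple[np.ndarray, np.ndarray]:
        """Fold the normalization into the convolution (inference only)."""
        if self.training:
            raise RuntimeError("branch fusion requires frozen statistics (eval mode)")
        scale, shift = self.bn.fold()
        w = self.conv.weight.data * scale[:, None, None, None]
        return w, shift


def softmax(z: np.ndarray, axis: int = -1) -> np.ndarray:
    z = z - z.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
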