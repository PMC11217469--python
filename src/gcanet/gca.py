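"""Grouped cascade attention (GCA).

A multi-head window attention variant designed to cut the redundancy and cost
of full multi-head self-attention on feature maps:

* **grouping** — the input channels are split into ``h`` contiguous slices and
  each head sees only its own slice (analogous to group convolution), so the
  q/k/v projections cost ``1/h`` of the full-width construction;
* **cascading** — the output of head ``j-1`` is added to the channel slice
  feeding head ``j`` before that head attends, deepening the computation
  without extra parameters;
* **windowing** — within each head, attention is computed independently over
  non-overlapping ``m x m`` spatial tiles, keeping cost linear in image area;
* **q-side local interaction** — a depthwise 3x3 convolution applied to the
  projected queries injects local structure before windowed attention.

Head outputs are concatenated channel-wise and mapped back to the input width
by a pointwise output projection.  Because the cascade adds a head *output* to
the next head's ``dim/h``-channel input slice, the per-head value width must
equal ``dim/h``; that is the default and the shape-consistent choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import ConfigurationError, ShapeError


@dataclass
class AttentionConfig:
    """Hyperparameters of one grouped-cascade-attention layer.

    Parameters
    ----------
    dim:
        Channel count of the block input (must be divisible by ``num_heads``).
    num_heads:
        Number of cascaded heads ``h``.
    key_dim:
        Per-head query/key embedding width.
    value_dim:
        Per-head value width; ``None`` (default) resolves to ``dim // num_heads``
        so the cascade addition is shape-consistent.
    window_size:
        Spatial edge ``m`` of each attention window.
    qk_scale:
        Multiplier on query–key dot products; ``None`` resolves to
        ``key_dim ** -0.5`` (standard scaled dot-product attention).
    q_local:
        Whether to apply the depthwise 3x3 local-interaction layer to the
        projected queries (residually) before windowing.
    pad_windows:
        If True, zero-pad bottom/right so non-divisible spatial sizes can be
        windowed, cropping after the merge; default is a hard error.
    """

    dim: int
    num_heads: int = 4
    key_dim: int = 16
    value_dim: int | None = None
    window_size: int = 7
    qk_scale: float | None = None
    q_local: bool = True
    pad_windows: bool = False

    def __post_init__(self) -> None:
        if self.dim % self.num_heads:
            raise ConfigurationError(
                f"dim={self.dim} is not divisible by num_heads={self.num_heads}"
            )
        if self.window_size < 1:
            raise ConfigurationError(f"window_size must be >= 1, got {self.window_size}")
        if self.key_dim < 1:
            raise ConfigurationError(f"key_dim must be >= 1, got {self.key_dim}")
        if self.value_dim is None:
            self.value_dim = self.dim // self.num_heads
        if self.value_dim < 1:
            raise ConfigurationError(f"value_dim must be >= 1, got {self.value_dim}")
        if self.value_dim != self.dim // self.num_heads:
            raise ConfigurationError(
                f"value_dim={self.value_dim} must equal dim/num_heads="
                f"{self.dim // self.num_heads} for the cascade addition"
            )
        if self.qk_scale is None:
            self.qk_scale = float(self.key_dim) ** -0.5


@dataclass
class WindowGrid:
    """Bookkeeping for an m x m window partition of an H x W feature map."""

    window_size: int
    rows: int
    cols: int
    height: int
    width: int
    pad_bottom: int = 0
    pad_right: int = 0

    @property
    def num_windows(self) -> int:
        return self.rows * self.cols


def split_heads(x: np.ndarray, h: int) -> list[np.ndarray]:
    """Split channels into ``h`` contiguous slices (head inputs), losslessly.

    Slice ``j`` holds channels ``[j*C/h, (j+1)*C/h)`` of the input; channel
    order is preserved so concatenating the slices reconstructs the input.
    """
    c = x.shape[1]
    if c % h:
        raise ConfigurationError(f"dim={c} is not divisible by num_heads={h}")
    step = c // h
    return [x[:, j * step : (j + 1) * step] for j in range(h)]


def window_partition(x: np.ndarray, m: int, pad: bool = False
                     ) -> tuple[np.ndarray, WindowGrid]:
    """Tile the spatial plane into non-overlapping ``m x m`` windows.

    Returns an array of shape ``(batch * n_windows, channels, m, m)`` with the
    windows of each batch item in row-major order, plus the grid needed to
    invert the operation.  When ``pad`` is set and the spatial size is not a
    multiple of ``m``, the map is zero-padded bottom/right first.
    """
    b, c, h, w = x.shape
    pb = (-h) % m
    pr = (-w) % m
    if (pb or pr) and not pad:
        raise ShapeError(
            f"spatial size {h}x{w} is not divisible by window_size={m} "
            "(enable padding to window anyway)"
        )
    if pb or pr:
        x = np.pad(x, ((0, 0), (0, 0), (0, pb), (0, pr)))
    rows, cols = (h + pb) // m, (w + pr) // m
    grid = WindowGrid(m, rows, cols, h, w, pb, pr)
    x = x.reshape(b, c, rows, m, cols, m)
    win = x.transpose(0, 2, 4, 1, 3, 5).reshape(b * rows * cols, c, m, m)
    return win, grid


def window_merge(windows: np.ndarray, grid: WindowGrid) -> np.ndarray:
    """Inverse of :func:`window_partition` (bit-exact on the unpadded region)."""
    m, rows, cols = grid.window_size, grid.rows, grid.cols
    n = rows * cols
    b = windows.shape[0] // n
    c = windows.shape[1]
    x = windows.reshape(b, rows, cols, c, m, m).transpose(0, 3, 1, 4, 2, 5)
    x = x.reshape(b, c, rows * m, cols * m)
    return x[:, :, : grid.height, : grid.width]


def single_head_window_attention(
    q: np.ndarray, k: np.ndarray, v: np.ndarray, scale: float
) -> tuple[np.ndarray, np.ndarray]:
    """Scaled dot-product attention over per-window token matrices.

    ``q``/``k`` are ``(n_windows, tokens, key_dim)``, ``v`` is
    ``(n_windows, tokens, value_dim)``.  Returns ``(output, attention)`` where
    each attention row is a softmax over the window's tokens.
    """
    if q.shape[:2] != k.shape[:2] or q.shape[:2] != v.shape[:2]:
        raise ShapeError(
            f"token counts differ between q {q.shape}, k {k.shape}, v {v.shape}"
        )
    attn = nn.softmax(scale * (q @ k.transpose(0, 2, 1)))
    t = q.shape[1]
    nn.record_macs(q.shape[0] * t * t * (q.shape[2] + v.shape[2]))
    return attn @ v, attn


def cascade_input(x_j: np.ndarray, prev_out: np.ndarray | None) -> np.ndarray:
    """Effective input of head ``j``: its slice plus the previous head's output.

    The first head (``prev_out is None``) attends to its raw slice.
    """
    if prev_out is None:
        return x_j
    if prev_out.shape != x_j.shape:
        raise ShapeError(
            f"cascade shape mismatch: slice {x_j.shape} vs previous output "
            f"{prev_out.shape}"
        )
    return x_j + prev_out


def _to_tokens(x: np.ndarray) -> np.ndarray:
    """(n, c, m, m) -> (n, m*m, c), row-major token order."""
    n, c, m1, m2 = x.shape
    return x.reshape(n, c, m1 * m2).transpose(0, 2, 1)


def _from_tokens(t: np.ndarray, m1: int, m2: int) -> np.ndarray:
    n, tk, c = t.shape
    return t.transpose(0, 2, 1).reshape(n, c, m1, m2)


class GroupedCascadeAttention(nn.Module):
    """The full GCA layer: split, cascade, project, window-attend, merge, project.

    Per head ``j``: the effective input (slice plus previous head's output) is
    projected to q/k/v by pointwise convolutions with batch normalization; the
    queries optionally pass a residual depthwise 3x3 local-interaction layer;
    q/k/v are partitioned into windows and attended independently per window;
    the merged head outputs are concatenated and mapped back to ``dim``
    channels by the output projection.
    """

    def __init__(self, cfg: AttentionConfig, rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        slice_dim = cfg.dim // cfg.num_heads
        self.q_proj = nn.ModuleList(
            nn.ConvBN(slice_dim, cfg.key_dim, 1, rng=rng) for _ in range(cfg.num_heads)
        )
        self.k_proj = nn.ModuleList(
            nn.ConvBN(slice_dim, cfg.key_dim, 1, rng=rng) for _ in range(cfg.num_heads)
        )
        self.v_proj = nn.ModuleList(
            nn.ConvBN(slice_dim, cfg.value_dim, 1, rng=rng) for _ in range(cfg.num_heads)
        )
        if cfg.q_local:
            self.q_dw = nn.ModuleList(
                nn.Conv2d(cfg.key_dim, cfg.key_dim, 3, padding=1,
                          groups=cfg.key_dim, bias=True, rng=rng)
                for _ in range(cfg.num_heads)
            )
        self.out_proj = nn.ConvBN(cfg.num_heads * cfg.value_dim, cfg.dim, 1, rng=rng)
        self._cache = None

    def forward(self, x: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        if x.shape[1] != cfg.dim:
            raise ShapeError(f"expected {cfg.dim} channels, got {x.shape[1]}")
        slices = split_heads(x, cfg.num_heads)
        outs: list[np.ndarray] = []
        caches = []
        prev = None
        for j in range(cfg.num_heads):
            xj = cascade_input(slices[j], prev)
            q = self.q_proj[j](xj)
            if cfg.q_local:
                q = q + self.q_dw[j](q)
            k = self.k_proj[j](xj)
            v = self.v_proj[j](xj)
            qw, grid = window_partition(q, cfg.window_size, cfg.pad_windows)
            kw, _ = window_partition(k, cfg.window_size, cfg.pad_windows)
            vw, _ = window_partition(v, cfg.window_size, cfg.pad_windows)
            qt, kt, vt = _to_tokens(qw), _to_tokens(kw), _to_tokens(vw)
            ot, attn = single_head_window_attention(qt, kt, vt, cfg.qk_scale)
            out = window_merge(_from_tokens(ot, cfg.window_size, cfg.window_size), grid)
            outs.append(out)
            if self.training:
                caches.append((qt, kt, vt, attn, grid))
            prev = out
        y = self.out_proj(np.concatenate(outs, axis=1))
        if self.training:
            self._cache = caches
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cfg = self.cfg
        caches = self._cache
        vdim = cfg.value_dim
        dcat = self.out_proj.backward(dy)
        d_outs = [dcat[:, j * vdim : (j + 1) * vdim] for j in range(cfg.num_heads)]
        dslices: list[np.ndarray | None] = [None] * cfg.num_heads
        d_from_next = None  # gradient flowing into head j's output via the cascade
        for j in range(cfg.num_heads - 1, -1, -1):
            qt, kt, vt, attn, grid = caches[j]
            d_out = d_outs[j] if d_from_next is None else d_outs[j] + d_from_next
            m = cfg.window_size
            dow, _ = window_partition(d_out, m, cfg.pad_windows)
            dot = _to_tokens(dow)
            dattn = dot @ vt.transpose(0, 2, 1)
            dvt = attn.transpose(0, 2, 1) @ dot
            ds = attn * (dattn - (dattn * attn).sum(axis=-1, keepdims=True))
            dqt = cfg.qk_scale * (ds @ kt)
            dkt = cfg.qk_scale * (ds.transpose(0, 2, 1) @ qt)
            dq = window_merge(_from_tokens(dqt, m, m), grid)
            dk = window_merge(_from_tokens(dkt, m, m), grid)
            dv = window_merge(_from_tokens(dvt, m, m), grid)
            if cfg.q_local:
                dq = dq + self.q_dw[j].backward(dq)
            dxj = (
                self.q_proj[j].backward(dq)
                + self.k_proj[j].backward(dk)
                + self.v_proj[j].backward(dv)
            )
            dslices[j] = dxj
            d_from_next = dxj  # via cascade_input of head j, grad reaches out_{j-1}
        self._cache = None
        return np.concatenate(dslices, axis=1)
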