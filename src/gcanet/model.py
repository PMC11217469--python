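"""Four-stage hybrid CNN-Transformer classification backbone.

Layout: a stride-2 stem convolution (3 -> ``stem_channels``), then four
stages.  Stage ``i`` is ``r_i`` EC blocks — the first downsamples by 2 and
raises the channel width, the rest keep shape and carry an identity branch —
followed by a single ET block at the stage's resolution.  A global average
pool and one fully connected layer produce the class logits.

The default channel schedule doubles across the first two stages and grows by
1.5x across the last two (128, 256, 384, 576), with EC repeats (2, 4, 14, 1)
concentrating depth in the penultimate stage; total spatial downsampling is
32x.  The defaults are sized for 224 x 224 inputs with 7 x 7 attention
windows, which divide every stage resolution evenly.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import nn
from .ec import ECBlock, ECBlockConfig
from .et import ETBlock, ETBlockConfig
from .gca import AttentionConfig
from .nn import ConfigurationError, ShapeError


def _per_stage(value, name: str) -> tuple[int, int, int, int]:
    if isinstance(value, int):
        return (value,) * 4
    value = tuple(int(v) for v in value)
    if len(value) != 4:
        raise ConfigurationError(f"{name} must be an int or a 4-tuple, got {value!r}")
    return value


@dataclass
class ModelConfig:
    """Full architecture hyperparameters.

    ``heads``, ``ec_groups``, ``key_dim``, ``n_ffn``, ``ffn_ratio`` and
    ``pe_groups`` accept either a single int (applied to every stage) or a
    per-stage 4-tuple.  The defaults are the calibrated configuration whose
    parameter/MAC totals match the published complexity of the architecture
    (~25.2 M parameters, ~6.4 G MACs at 224 x 224, 3 classes).
    """

    num_classes: int = 3
    stem_channels: int = 64
    stage_channels: tuple[int, int, int, int] = (128, 256, 384, 576)
    ec_repeats: tuple[int, int, int, int] = (2, 4, 14, 1)
    window_size: int = 7
    heads: int | tuple[int, int, int, int] = 4
    key_dim: int | tuple[int, int, int, int] = 16
    ec_groups: int | tuple[int, int, int, int] = (8, 8, 4, 2)
    n_ffn: int | tuple[int, int, int, int] = 2
    ffn_ratio: int | tuple[int, int, int, int] = 3
    pe_groups: int | tuple[int, int, int, int] = (4, 4, 8, 4)
    input_size: int = 224
    pad_windows: bool = False
    q_local: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.stage_channels = tuple(int(c) for c in self.stage_channels)
        self.ec_repeats = tuple(int(r) for r in self.ec_repeats)
        if len(self.stage_channels) != 4 or len(self.ec_repeats) != 4:
            raise ConfigurationError("stage_channels and ec_repeats must have 4 entries")
        c = self.stage_channels
        if 2 * c[2] != 3 * c[1] or 2 * c[3] != 3 * c[2]:
            raise ConfigurationError(
                f"stage_channels={c}: stages 3 and 4 must be 1.5x the previous stage"
            )
        if max(self.ec_repeats) != self.ec_repeats[2]:
            raise ConfigurationError(
                f"ec_repeats={self.ec_repeats}: the penultimate stage must be deepest"
            )
        if min(self.ec_repeats) < 1:
            raise ConfigurationError(f"ec_repeats={self.ec_repeats}: all must be >= 1")
        if self.num_classes < 2:
            raise ConfigurationError(f"num_classes must be >= 2, got {self.num_classes}")
        if not self.pad_windows:
            for i in range(4):
                res = self.input_size // (2 ** (i + 2))
                if res % self.window_size:
                    raise ConfigurationError(
                        f"stage {i + 1} resolution {res} (input_size="
                        f"{self.input_size}) is not divisible by window_size="
                        f"{self.window_size}; enable pad_windows or adjust"
                    )

    # -- per-stage views ----------------------------------------------------
    def stage_heads(self) -> tuple[int, ...]:
        return _per_stage(self.heads, "heads")

    def stage_key_dim(self) -> tuple[int, ...]:
        return _per_stage(self.key_dim, "key_dim")

    def stage_ec_groups(self) -> tuple[int, ...]:
        return _per_stage(self.ec_groups, "ec_groups")

    def stage_n_ffn(self) -> tuple[int, ...]:
        return _per_stage(self.n_ffn, "n_ffn")

    def stage_ffn_ratio(self) -> tuple[int, ...]:
        return _per_stage(self.ffn_ratio, "ffn_ratio")

    def stage_pe_groups(self) -> tuple[int, ...]:
        return _per_stage(self.pe_groups, "pe_groups")

    def et_config(self, stage: int) -> ETBlockConfig:
        dim = self.stage_channels[stage]
        attn = AttentionConfig(
            dim=dim,
            num_heads=self.stage_heads()[stage],
            key_dim=self.stage_key_dim()[stage],
            window_size=self.window_size,
            q_local=self.q_local,
            pad_windows=self.pad_windows,
        )
        return ETBlockConfig(
            dim=dim,
            n_ffn=self.stage_n_ffn()[stage],
            ffn_ratio=self.stage_ffn_ratio()[stage],
            pe_groups=self.stage_pe_groups()[stage],
            attention=attn,
        )

    # -- (de)serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown ModelConfig fields: {sorted(unknown)}")
        d = dict(d)
        for key in ("stage_channels", "ec_repeats", "heads", "key_dim",
                    "ec_groups", "n_ffn", "ffn_ratio", "pe_groups"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)


def tiny_config(num_classes: int = 2, input_size: int = 64) -> ModelConfig:
    """A width-reduced preset (channels / 8, repeats (1,1,2,1)) for fast tests."""
    return ModelConfig(
        num_classes=num_classes,
        stem_channels=8,
        stage_channels=(16, 32, 48, 72),
        ec_repeats=(1, 1, 2, 1),
        window_size=2,
        heads=2,
        key_dim=4,
        ec_groups=(2, 2, 2, 2),
        n_ffn=1,
        ffn_ratio=2,
        pe_groups=2,
        input_size=input_size,
    )


class Stage(nn.Module):
    """One backbone stage: downsampling EC, (r-1) shape-preserving ECs, one ET."""

    def __init__(self, in_channels: int, out_channels: int, repeats: int,
                 ec_groups: int, et_cfg: ETBlockConfig,
                 rng: np.random.Generator) -> None:
        super().__init__()
        blocks = [ECBlock(ECBlockConfig(in_channels, out_channels, stride=2,
                                        groups=ec_groups), rng)]
        for _ in range(repeats - 1):
            blocks.append(ECBlock(ECBlockConfig(out_channels, out_channels,
                                                stride=1, groups=ec_groups), rng))
        self.ec_blocks = nn.ModuleList(blocks)
        self.et_block = ETBlock(et_cfg, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        for block in self.ec_blocks:
            x = block(x)
        return self.et_block(x)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dy = self.et_block.backward(dy)
        for block in reversed(self.ec_blocks):
            dy = block.backward(dy)
        return dy


class Stem(nn.Module):
    """Stride-2 3x3 convolution from RGB to the base width, with BN + ReLU."""

    def __init__(self, out_channels: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.conv = nn.ConvBN(3, out_channels, 3, stride=2, padding=1, rng=rng)
        self.relu = nn.ReLU()

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.relu(self.conv(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.conv.backward(self.relu.backward(dy))


class Head(nn.Module):
    """Global average pooling followed by one fully connected layer."""

    def __init__(self, in_channels: int, num_classes: int,
                 rng: np.random.Generator) -> None:
        super().__init__()
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(in_channels, num_classes, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.fc(self.pool(x))

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return self.pool.backward(self.fc.backward(dy))


class Model(nn.Module):
    """The assembled classifier: stem -> 4 stages -> pooled linear head."""

    def __init__(self, cfg: ModelConfig) -> None:
        super().__init__()
        rng = np.random.default_rng(cfg.seed)
        self.cfg = cfg
        self.stem = Stem(cfg.stem_channels, rng)
        stages = []
        c_in = cfg.stem_channels
        for i in range(4):
            stages.append(Stage(c_in, cfg.stage_channels[i], cfg.ec_repeats[i],
                                cfg.stage_ec_groups()[i], cfg.et_config(i), rng))
            c_in = cfg.stage_channels[i]
        self.stages = nn.ModuleList(stages)
        self.head = Head(cfg.stage_channels[3], cfg.num_classes, rng)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.head(self.forward_features(x)[-1])

    def forward_features(self, x: np.ndarray) -> list[np.ndarray]:
        """Return the per-stage feature maps F2..F5 (after each stage)."""
        if x.ndim != 4 or x.shape[1] != 3:
            raise ShapeError(f"expected (batch, 3, H, W) input, got {x.shape}")
        if min(x.shape[2], x.shape[3]) < 32:
            raise ShapeError(f"input spatial size {x.shape[2:]} is below 32")
        x = self.stem(x)
        feats = []
        for stage in self.stages:
            x = stage(x)
            feats.append(x)
        return feats

    def backward(self, dlogits: np.ndarray) -> np.ndarray:
        dy = self.head.backward(dlogits)
        for stage in reversed(self.stages):
            dy = stage.backward(dy)
        return self.stem.backward(dy)

    def segments(self):
        """(name, module) pairs in forward order, for complexity breakdown."""
        yield "stem", self.stem
        for i, stage in enumerate(self.stages):
            yield f"stage{i + 1}", stage
        yield "head", self.head

    def fuse_(self) -> None:
        """Structurally reparameterize every EC block for inference."""
        self.eval()
        for m in self.modules():
            if isinstance(m, ECBlock):
                m.fuse_()


def build_model(cfg: ModelConfig) -> Model:
    return Model(cfg)


# ---------------------------------------------------------------------------
# Checkpoints


class CheckpointMismatchError(RuntimeError):
    """The checkpoint's embedded configuration differs from the model's."""


def save_checkpoint(model: Model, path, fused: bool = False) -> None:
    """Persist weights, running statistics and the embedded configuration."""
    meta = {"config": model.cfg.to_dict(), "fused": bool(fused)}
    np.savez(path, __meta__=np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8),
             **model.state_dict())


def load_checkpoint(path, model: Model | None = None) -> Model:
    """Restore a model from ``path``.

    With ``model`` given, its configuration must match the checkpoint's
    (raises :class:`CheckpointMismatchError` otherwise); without, a fresh
    model is built from the embedded configuration.
    """
    with np.load(path) as data:
        meta = json.loads(bytes(data["__meta__"]).decode())
        state = {k: data[k] for k in data.files if k != "__meta__"}
    cfg = ModelConfig.from_dict(meta["config"])
    if model is not None and model.cfg != cfg:
        diffs = [
            f"{k}: checkpoint={getattr(cfg, k)!r} model={getattr(model.cfg, k)!r}"
            for k in cfg.__dataclass_fields__
            if getattr(cfg, k) != getattr(model.cfg, k)
        ]
        raise CheckpointMismatchError("; ".join(diffs))
    if model is None:
        model = build_model(cfg)
    model.load_state_dict(state)
    if meta.get("fused"):
        model.fuse_()
    return model
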