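"""Analytic parameter and multiply-accumulate (MAC) accounting.

Parameters are counted by enumerating every learnable array (convolution and
linear weights, biases, normalization affine terms).  MACs are counted by
tracing a single image through the network while each MAC-bearing layer
reports its analytic cost — ``k^2 * Cin/g * Cout * Hout * Wout`` per
convolution, ``in * out`` per position for pointwise/linear maps, and the
``q k^T`` / ``attn v`` matrix products per window and head for attention.
Normalization and activations are excluded, following the convention under
which one multiply-accumulate is reported as one "FLOP" in the vision
literature; the numbers printed here are MACs and are labelled as such.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .model import Model


@dataclass
class ComplexityReport:
    """Totals plus a per-segment breakdown for a stated input size."""

    total_params: int
    total_macs: int
    input_size: int
    breakdown: list[tuple[str, int, int]]  # (segment, params, macs)

    @property
    def params_millions(self) -> float:
        return self.total_params / 1e6

    @property
    def macs_billions(self) -> float:
        return self.total_macs / 1e9

    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "total_params": self.total_params,
            "total_macs": self.total_macs,
            "params_millions": round(self.params_millions, 3),
            "macs_billions": round(self.macs_billions, 3),
            "breakdown": [
                {"segment": name, "params": p, "macs": m}
                for name, p, m in self.breakdown
            ],
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    def __str__(self) -> str:
        lines = [f"{'segment':<10}{'params':>14}{'MACs':>16}"]
        for name, p, m in self.breakdown:
            lines.append(f"{name:<10}{p:>14,}{m:>16,}")
        lines.append(f"{'total':<10}{self.total_params:>14,}{self.total_macs:>16,}")
        lines.append(
            f"= {self.params_millions:.1f} M params, "
            f"{self.macs_billions:.1f} G MACs @ {self.input_size}x{self.input_size}"
        )
        return "\n".join(lines)


def count_parameters(module: nn.Module) -> int:
    """Total element count over all learnable arrays of ``module``."""
    return sum(p.size for p in module.parameters())


def count_macs(model: Model, input_size: int | None = None) -> int:
    """Multiply-accumulate count for one image at ``input_size``."""
    return complexity_report(model, input_size).total_macs


def complexity_report(model: Model, input_size: int | None = None) -> ComplexityReport:
    """Trace one zero image through the model, accounting per segment."""
    size = int(input_size or model.cfg.input_size)
    was_training = model.training
    model.eval()
    x = np.zeros((1, 3, size, size))
    rows = []
    for name, segment in model.segments():
        with nn.MacCounter() as counter:
            x = segment(x)
        rows.append((name, count_parameters(segment), counter.total))
    if was_training:
        model.train()
    return ComplexityReport(
        total_params=sum(r[1] for r in rows),
        total_macs=sum(r[2] for r in rows),
        input_size=size,
        breakdown=rows,
    )
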