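"""Weighted hybrid dilated convolution (WHDC) block.

Four 3x3 dilated convolutions (rates 3, 6, 9, 18 by default), each followed
by batch normalisation and GELU, connected in cascade: branch k consumes
branch k-1's output.  Each branch output is rescaled by a scalar gate in
(0, 1) computed from its own globally pooled features through a learned
linear map and a sigmoid ("self-weighting").  The four gated maps and the
block input are concatenated (5C channels), passed through squeeze-and-
excitation channel attention with reduction ratio 16, and projected back to
C channels with a 1x1 convolution, so the block preserves C, H and W and
can sit at the end of an encoder stage.  Padding equals the dilation rate,
which keeps resolution for a 3x3 kernel while widening the receptive field
(effective span = kernel + (kernel-1)(rate-1)).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .nn import BatchNorm2d, Conv2d, Linear, Module, ModuleList, Tensor, concat
from .nn import functional as F

__all__ = ["WHDCConfig", "DilatedBranch", "ChannelAttention", "WHDCBlock"]


@dataclasses.dataclass
class WHDCConfig:
    channels: int
    dilation_rates: tuple[int, ...] = (3, 6, 9, 18)
    kernel: int = 3
    reduction_ratio: int = 16

    def __post_init__(self):
        rates = tuple(self.dilation_rates)
        if any(r <= 0 for r in rates) or any(b <= a for a, b in zip(rates, rates[1:])):
            raise ValueError(f"dilation rates must be positive and strictly increasing: {rates}")
        if self.channels < 1:
            raise ValueError("channels must be >= 1")
        self.dilation_rates = rates


class DilatedBranch(Module):
    """conv(3x3, dilation=rate, padding=rate) -> batch norm -> GELU."""

    def __init__(self, channels: int, rate: int, kernel: int = 3, *, rng: np.random.Generator):
        super().__init__()
        self.channels = channels
        pad = rate * (kernel - 1) // 2
        self.conv = Conv2d(channels, channels, kernel, padding=pad, dilation=rate, rng=rng)
        self.bn = BatchNorm2d(channels)

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {x.shape[1]}")
        return self.bn(self.conv(x)).gelu()


class BranchGate(Module):
    """Scalar gate in (0,1) from the branch's own pooled features."""

    def __init__(self, channels: int, *, rng: np.random.Generator):
        super().__init__()
        self.fc = Linear(channels, 1, rng=rng)

    def forward(self, branch_out: Tensor) -> Tensor:
        pooled = F.global_avg_pool(branch_out)  # (N, C)
        return self.fc(pooled).sigmoid()  # (N, 1)


class ChannelAttention(Module):
    """Squeeze-and-excitation: GAP -> FC(C -> C/r) -> ReLU -> FC -> sigmoid,
    per-channel scales multiplied into the input."""

    def __init__(self, channels: int, reduction_ratio: int = 16, *, rng: np.random.Generator):
        super().__init__()
        if channels < reduction_ratio:
            raise ValueError(
                f"channels ({channels}) must be >= reduction_ratio ({reduction_ratio})"
            )
        hidden = max(1, channels // reduction_ratio)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        scale = self.fc2(self.fc1(F.global_avg_pool(x)).relu()).sigmoid()
        return x * scale.reshape(n, c, 1, 1)


class WHDCBlock(Module):
    def __init__(self, cfg: WHDCConfig, *, rng: np.random.Generator):
        super().__init__()
        self.cfg = cfg
        c = cfg.channels
        self.branches = ModuleList(
            DilatedBranch(c, r, cfg.kernel, rng=rng) for r in cfg.dilation_rates
        )
        self.gates = ModuleList(BranchGate(c, rng=rng) for _ in cfg.dilation_rates)
        cat_channels = (len(cfg.dilation_rates) + 1) * c
        self.attention = ChannelAttention(cat_channels, cfg.reduction_ratio, rng=rng)
        self.project = Conv2d(cat_channels, c, 1, rng=rng)

    def branch_gates(self, x: Tensor) -> list[float]:
        """Gate values for a given input (diagnostic; inference mode)."""
        feats, gates = self._cascade(x)
        return [float(g.data.mean()) for g in gates]

    def _cascade(self, x: Tensor) -> tuple[list[Tensor], list[Tensor]]:
        feats = []
        cur = x
        for branch in self.branches:
            cur = branch(cur)
            feats.append(cur)
        gates = [gate(f) for gate, f in zip(self.gates, feats)]
        return feats, gates

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.cfg.channels:
            raise ValueError(f"expected {self.cfg.channels} channels, got {x.shape[1]}")
        n = x.shape[0]
        feats, gates = self._cascade(x)
        weighted = [f * g.reshape(n, 1, 1, 1) for f, g in zip(feats, gates)]
        cat = concat(weighted + [x], axis=1)
        return self.project(self.attention(cat))
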