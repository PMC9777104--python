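"""Staining-invariant encoder: a five-stage hybrid conv/transformer backbone.

Stage layout (each stage halves the spatial side, so side(s_k) =
input_size / 2^(k+1)):

* S0 — conv stem: two 3x3 convolutions (first with stride 2), each with
  batch norm + GELU, closed by a WHDC block;
* S1 — MBConv (inverted-residual, depthwise-separable with squeeze-and-
  excitation) blocks, closed by a WHDC block;
* S2 — identical MBConv stage without WHDC;
* S3, S4 — transformer stages: stride-2 max-pool + 1x1 projection at entry,
  then pre-norm blocks of multi-head self-attention with a learned 2D
  relative position bias and an FFN, both residual.

The hybrid scale follows the published CoAtNet-0 configuration for the
``full`` preset; the ``tiny`` preset keeps the same topology at widths that
train in seconds on a CPU.  For a 256 input the S4 bottleneck map is 8x8;
``encode`` additionally returns its global average pool as the bottleneck
vector.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm2d,
    Conv2d,
    LayerNorm,
    Linear,
    Module,
    ModuleList,
    Parameter,
    Tensor,
)
from .nn import functional as F
from .whdc import WHDCBlock, WHDCConfig

__all__ = ["EncoderConfig", "StageOutputs", "SIEEncoder", "MBConv", "TransformerStage",
           "dump_stage_heatmaps"]

_PRESETS = {
    "full": {"stage_channels": (64, 96, 192, 384, 768), "stage_depths": (2, 2, 3, 5, 2), "attention_heads": 8},
    "tiny": {"stage_channels": (16, 24, 32, 64, 128), "stage_depths": (1, 1, 1, 1, 1), "attention_heads": 2},
}


@dataclasses.dataclass
class EncoderConfig:
    stage_channels: tuple[int, ...] = _PRESETS["full"]["stage_channels"]
    stage_depths: tuple[int, ...] = _PRESETS["full"]["stage_depths"]
    attention_heads: int = 8
    input_size: int = 256
    dilation_rates: tuple[int, ...] = (3, 6, 9, 18)
    whdc_reduction_ratio: int = 16
    preset: str = "full"

    def __post_init__(self):
        self.stage_channels = tuple(self.stage_channels)
        self.stage_depths = tuple(self.stage_depths)
        self.dilation_rates = tuple(self.dilation_rates)
        if len(self.stage_channels) != 5 or len(self.stage_depths) != 5:
            raise ValueError("stage_channels and stage_depths must list 5 stages")
        if self.input_size % 32:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")
        if any(b < a for a, b in zip(self.stage_channels, self.stage_channels[1:])):
            raise ValueError("stage_channels must be nondecreasing")

    @classmethod
    def from_preset(cls, preset: str = "full", input_size: int = 256, **overrides) -> "EncoderConfig":
        if preset not in _PRESETS:
            raise ValueError(f"unknown preset {preset!r}; choose from {sorted(_PRESETS)}")
        kw = dict(_PRESETS[preset])
        kw.update(overrides)
        return cls(input_size=input_size, preset=preset, **kw)

    def whdc_config(self, channels: int) -> WHDCConfig:
        return WHDCConfig(
            channels=channels,
            dilation_rates=self.dilation_rates,
            reduction_ratio=self.whdc_reduction_ratio,
        )

    def stage_side(self, k: int) -> int:
        return self.input_size // 2 ** (k + 1)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclasses.dataclass
class StageOutputs:
    """Feature maps from the five stages plus the pooled bottleneck vector."""

    s0: Tensor
    s1: Tensor
    s2: Tensor
    s3: Tensor
    s4: Tensor
    bottleneck: Tensor  # (N, C4) global average of s4

    def maps(self) -> list[Tensor]:
        return [self.s0, self.s1, self.s2, self.s3, self.s4]


class SqueezeExcite(Module):
    def __init__(self, channels: int, hidden: int, *, rng: np.random.Generator):
        super().__init__()
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        n, c = x.shape[0], x.shape[1]
        s = self.fc2(self.fc1(F.global_avg_pool(x)).gelu()).sigmoid()
        return x * s.reshape(n, c, 1, 1)


class MBConv(Module):
    """Inverted residual block: 1x1 expand (x4) -> 3x3 depthwise -> SE ->
    1x1 project, with a residual connection when shapes match."""

    def __init__(self, in_ch: int, out_ch: int, stride: int, *, rng: np.random.Generator,
                 expansion: int = 4):
        super().__init__()
        hidden = in_ch * expansion
        self.stride = stride
        self.use_residual = stride == 1 and in_ch == out_ch
        self.expand = Conv2d(in_ch, hidden, 1, rng=rng)
        self.bn1 = BatchNorm2d(hidden)
        self.depthwise = Conv2d(hidden, hidden, 3, stride=stride, padding=1, groups=hidden, rng=rng)
        self.bn2 = BatchNorm2d(hidden)
        self.se = SqueezeExcite(hidden, max(1, in_ch // 4), rng=rng)
        self.project = Conv2d(hidden, out_ch, 1, rng=rng)
        self.bn3 = BatchNorm2d(out_ch)

    def forward(self, x: Tensor) -> Tensor:
        y = self.bn1(self.expand(x)).gelu()
        y = self.bn2(self.depthwise(y)).gelu()
        y = self.se(y)
        y = self.bn3(self.project(y))
        return x + y if self.use_residual else y


def relative_index(h: int, w: int) -> np.ndarray:
    """(L, L) lookup into a (2h-1)(2w-1) relative-offset bias table."""
    coords = np.stack(np.meshgrid(np.arange(h), np.arange(w), indexing="ij"), axis=-1).reshape(-1, 2)
    rel = coords[:, None, :] - coords[None, :, :]  # (L, L, 2)
    return (rel[..., 0] + h - 1) * (2 * w - 1) + (rel[..., 1] + w - 1)


class RelativeAttention(Module):
    """Multi-head self-attention over a fixed 2D grid with a learned
    relative position bias indexed by row/column offset."""

    def __init__(self, dim: int, heads: int, grid: tuple[int, int], *, rng: np.random.Generator):
        super().__init__()
        if dim % heads:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.heads, self.dim = heads, dim
        self.head_dim = dim // heads
        self.grid = grid
        self.qkv = Linear(dim, 3 * dim, rng=rng)
        self.proj = Linear(dim, dim, rng=rng)
        h, w = grid
        self._index = relative_index(h, w)
        self.bias = Parameter(np.zeros((heads, (2 * h - 1) * (2 * w - 1))))

    def forward(self, x: Tensor) -> Tensor:
        n, L, c = x.shape
        if L != self._index.shape[0]:
            raise ValueError(
                f"sequence length {L} does not match relative-bias grid {self.grid}"
            )
        qkv = self.qkv(x)  # (N, L, 3C)
        q = qkv[:, :, 0:c].reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        k = qkv[:, :, c : 2 * c].reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        v = qkv[:, :, 2 * c : 3 * c].reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        scores = scores + self.bias.index_last(self._index)  # (h, L, L) broadcast over N
        attn = scores.softmax(-1)
        out = (attn @ v).transpose(0, 2, 1, 3).reshape(n, L, c)
        return self.proj(out)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """(N, heads, L, L) softmax weights (diagnostic)."""
        n, L, c = x.shape
        qkv = self.qkv(x)
        q = qkv[:, :, 0:c].reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        k = qkv[:, :, c : 2 * c].reshape(n, L, self.heads, self.head_dim).transpose(0, 2, 1, 3)
        scores = (q @ k.transpose(0, 1, 3, 2)) * (1.0 / np.sqrt(self.head_dim))
        scores = scores + self.bias.index_last(self._index)
        return scores.softmax(-1).data


class TransformerBlock(Module):
    def __init__(self, dim: int, heads: int, grid: tuple[int, int], *, rng: np.random.Generator,
                 ffn_expansion: int = 4):
        super().__init__()
        self.norm1 = LayerNorm(dim)
        self.attn = RelativeAttention(dim, heads, grid, rng=rng)
        self.norm2 = LayerNorm(dim)
        self.ffn1 = Linear(dim, ffn_expansion * dim, rng=rng)
        self.ffn2 = Linear(ffn_expansion * dim, dim, rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = x + self.attn(self.norm1(x))
        x = x + self.ffn2(self.ffn1(self.norm2(x)).gelu())
        return x


class TransformerStage(Module):
    """Stride-2 max-pool + 1x1 channel projection, then transformer blocks."""

    def __init__(self, in_ch: int, out_ch: int, depth: int, heads: int,
                 grid: tuple[int, int], *, rng: np.random.Generator):
        super().__init__()
        self.proj = Conv2d(in_ch, out_ch, 1, rng=rng)
        self.blocks = ModuleList(
            TransformerBlock(out_ch, heads, grid, rng=rng) for _ in range(depth)
        )

    def forward(self, x: Tensor) -> Tensor:
        x = self.proj(F.max_pool2d(x, 2))
        n, c, h, w = x.shape
        tokens = x.reshape(n, c, h * w).transpose(0, 2, 1)  # (N, L, C)
        for blk in self.blocks:
            tokens = blk(tokens)
        return tokens.transpose(0, 2, 1).reshape(n, c, h, w)


class ConvStem(Module):
    """S0: two 3x3 convolutions (first stride 2) with BN + GELU, then WHDC."""

    def __init__(self, cfg: EncoderConfig, *, rng: np.random.Generator):
        super().__init__()
        c0 = cfg.stage_channels[0]
        self.conv1 = Conv2d(3, c0, 3, stride=2, padding=1, rng=rng)
        self.bn1 = BatchNorm2d(c0)
        self.conv2 = Conv2d(c0, c0, 3, padding=1, rng=rng)
        self.bn2 = BatchNorm2d(c0)
        self.whdc = WHDCBlock(cfg.whdc_config(c0), rng=rng)

    def forward(self, x: Tensor) -> Tensor:
        x = self.bn1(self.conv1(x)).gelu()
        x = self.bn2(self.conv2(x)).gelu()
        return self.whdc(x)


class SIEEncoder(Module):
    """Five-stage staining-invariant encoder (see module docstring)."""

    def __init__(self, cfg: EncoderConfig, *, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        ch = cfg.stage_channels
        d = cfg.stage_depths
        self.s0 = ConvStem(cfg, rng=rng)

        def mb_stage(cin, cout, depth):
            blocks = [MBConv(cin, cout, stride=2, rng=rng)]
            blocks += [MBConv(cout, cout, stride=1, rng=rng) for _ in range(depth - 1)]
            return ModuleList(blocks)

        self.s1_blocks = mb_stage(ch[0], ch[1], d[1])
        self.s1_whdc = WHDCBlock(cfg.whdc_config(ch[1]), rng=rng)
        self.s2_blocks = mb_stage(ch[1], ch[2], d[2])
        g3 = cfg.stage_side(3)
        g4 = cfg.stage_side(4)
        self.s3 = TransformerStage(ch[2], ch[3], d[3], cfg.attention_heads, (g3, g3), rng=rng)
        self.s4 = TransformerStage(ch[3], ch[4], d[4], cfg.attention_heads, (g4, g4), rng=rng)

    # ------------------------------------------------------------- stages
    def conv_stem(self, x: Tensor) -> Tensor:
        if x.shape[2] != self.cfg.input_size or x.shape[3] != self.cfg.input_size:
            raise ValueError(
                f"expected {self.cfg.input_size}x{self.cfg.input_size} input, "
                f"got {x.shape[2]}x{x.shape[3]}"
            )
        return self.s0(x)

    def mbconv_stage(self, x: Tensor, stage_index: int) -> Tensor:
        if stage_index not in (1, 2):
            raise ValueError("MBConv stages are 1 and 2")
        blocks = self.s1_blocks if stage_index == 1 else self.s2_blocks
        for blk in blocks:
            x = blk(x)
        if stage_index == 1:
            x = self.s1_whdc(x)
        return x

    def transformer_stage(self, x: Tensor, stage_index: int) -> Tensor:
        if stage_index not in (3, 4):
            raise ValueError("transformer stages are 3 and 4")
        return (self.s3 if stage_index == 3 else self.s4)(x)

    def forward(self, x) -> StageOutputs:
        return self.encode(x)

    def encode(self, x) -> StageOutputs:
        """Run S0..S4 on an (N, 3, H, W) tensor (or an (H, W, 3) image)."""
        if not isinstance(x, Tensor):
            arr = np.asarray(x)
            if arr.ndim == 3 and arr.shape[-1] == 3:
                arr = arr.transpose(2, 0, 1)[None]
            x = Tensor(arr.astype(np.float32))
        s0 = self.conv_stem(x)
        s1 = self.mbconv_stage(s0, 1)
        s2 = self.mbconv_stage(s1, 2)
        s3 = self.transformer_stage(s2, 3)
        s4 = self.transformer_stage(s3, 4)
        return StageOutputs(s0, s1, s2, s3, s4, bottleneck=F.global_avg_pool(s4))


def dump_stage_heatmaps(stages: StageOutputs, out_dir) -> list[Path]:
    """Write per-stage channel-mean heatmaps (min-max normalised PNGs)."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for k, fm in enumerate(stages.maps()):
        m = fm.data[0].mean(axis=0)
        rng_ = m.max() - m.min()
        norm = (m - m.min()) / rng_ if rng_ > 0 else np.zeros_like(m)
        p = out_dir / f"stage_s{k}.png"
        iio.imwrite(p, np.rint(norm * 255).astype(np.uint8))
        paths.append(p)
    return paths
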