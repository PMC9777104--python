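"""Downstream nuclei segmentation network and its training loop.

The pretrained staining-invariant encoder supplies stage features; a
five-layer decoder reconstructs a full-resolution foreground probability
map.  Each decoder layer is a 4x4 stride-2 transposed convolution (batch
norm + ReLU on all but the last); before each of the first four transposed
convolutions the matching encoder stage (s3, s2, s1, s0 going outward) is
fused by concatenation after passing through an additive attention gate,
which suppresses skip activations that the coarser decoder state deems
irrelevant.  The last layer maps to one channel and a sigmoid; masks come
from thresholding at 0.5 (pixel = 1 when probability >= threshold).

Training minimises a convex combination of binary cross-entropy and Dice
loss, ``gamma * BCE + (1 - gamma) * Dice`` with gamma = 0.4, under Adam
(lr 2e-4, betas (0.5, 0.999)).
"""

from __future__ import annotations

import csv
import dataclasses
from pathlib import Path

import numpy as np

from . import data_pipeline as dp
from .nn import (
    Adam,
    BatchNorm2d,
    Conv2d,
    ConvTranspose2d,
    Module,
    ModuleList,
    Tensor,
    concat,
    load_checkpoint,
    save_checkpoint,
)
from .nn import functional as F
from .sie_encoder import EncoderConfig, SIEEncoder, StageOutputs

__all__ = [
    "SegConfig",
    "AttentionGate",
    "Decoder",
    "SegModel",
    "bce_loss",
    "dice_loss",
    "combined_loss",
    "train_segmentation",
    "predict_mask",
    "write_prediction_overlay",
]

_BCE_EPS = 1e-7
_DICE_SMOOTH = 1e-6


@dataclasses.dataclass
class SegConfig:
    decoder_channels: tuple[int, ...] | None = None  # default mirrors encoder
    threshold: float = 0.5
    gamma: float = 0.4
    lr: float = 0.0002
    betas: tuple[float, float] = (0.5, 0.999)
    epochs: int = 100
    batch_size: int = 4
    freeze_encoder: bool = False
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must be in [0, 1]")
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must be in (0, 1)")


class AttentionGate(Module):
    """Additive attention over a skip connection.

    1x1 maps bring the skip and the (2x nearest-upsampled) gating signal to
    a common width; their ReLU'd sum passes through a 1x1 map and a sigmoid
    to give per-pixel coefficients in (0, 1) that rescale the skip.
    """

    def __init__(self, skip_ch: int, gate_ch: int, inter_ch: int | None = None,
                 *, rng: np.random.Generator):
        super().__init__()
        inter_ch = inter_ch or max(1, skip_ch // 2)
        self.w_skip = Conv2d(skip_ch, inter_ch, 1, bias=False, rng=rng)
        self.w_gate = Conv2d(gate_ch, inter_ch, 1, bias=True, rng=rng)
        self.psi = Conv2d(inter_ch, 1, 1, bias=True, rng=rng)

    def forward(self, skip: Tensor, gating: Tensor) -> Tensor:
        if gating.shape[2] > skip.shape[2] or gating.shape[3] > skip.shape[3]:
            raise ValueError("gating signal must be spatially <= skip")
        g = self.w_gate(gating)
        while g.shape[2] < skip.shape[2]:
            g = F.upsample_nearest2x(g)
        if g.shape[2] != skip.shape[2] or g.shape[3] != skip.shape[3]:
            raise ValueError(
                f"skip {skip.shape} and gating {gating.shape} sizes are not "
                "related by a power of two"
            )
        coeff = self.psi((self.w_skip(skip) + g).relu()).sigmoid()  # (N,1,H,W)
        return skip * coeff


class Decoder(Module):
    """Five transposed-conv layers from the 8x8 bottleneck to a
    full-resolution 1-channel sigmoid probability map."""

    def __init__(self, encoder_cfg: EncoderConfig, decoder_channels=None,
                 *, rng: np.random.Generator):
        super().__init__()
        ch = encoder_cfg.stage_channels
        dec = tuple(decoder_channels) if decoder_channels else (ch[3], ch[2], ch[1], ch[0], 1)
        if len(dec) != 5:
            raise ValueError("decoder_channels must list 5 layers")
        self.dec = dec
        skips = (ch[3], ch[2], ch[1], ch[0])  # s3, s2, s1, s0
        gates_in = (ch[4], dec[0] + ch[3], dec[1] + ch[2], dec[2] + ch[1])
        self.upconvs = ModuleList()
        self.bns = ModuleList()
        self.gates = ModuleList()
        in_ch = ch[4]
        for k in range(4):
            self.upconvs.append(ConvTranspose2d(in_ch, dec[k], 4, 2, 1, rng=rng))
            self.bns.append(BatchNorm2d(dec[k]))
            self.gates.append(AttentionGate(skips[k], gates_in[k], rng=rng))
            in_ch = dec[k] + skips[k]
        self.final = ConvTranspose2d(in_ch, 1, 4, 2, 1, rng=rng)

    def forward(self, stages: StageOutputs) -> Tensor:
        skips = [stages.s3, stages.s2, stages.s1, stages.s0]
        x = stages.s4
        for k in range(4):
            up = self.bns[k](self.upconvs[k](x)).relu()
            gated = self.gates[k](skips[k], x)
            if up.shape[2] != gated.shape[2]:
                raise ValueError(
                    f"decoder layer {k + 1}: upsampled size {up.shape[2]} does not "
                    f"match skip size {gated.shape[2]}"
                )
            x = concat([up, gated], axis=1)
        return self.final(x).sigmoid()


class SegModel(Module):
    def __init__(self, encoder_cfg: EncoderConfig, seg_cfg: SegConfig | None = None,
                 *, rng: np.random.Generator | int = 0):
        super().__init__()
        if not isinstance(rng, np.random.Generator):
            rng = np.random.default_rng(rng)
        self.encoder_cfg = encoder_cfg
        self.seg_cfg = seg_cfg or SegConfig()
        self.encoder = SIEEncoder(encoder_cfg, rng=rng)
        self.decoder = Decoder(encoder_cfg, self.seg_cfg.decoder_channels, rng=rng)

    def forward(self, x) -> Tensor:
        return self.decoder(self.encoder.encode(x))

    def load_encoder_checkpoint(self, path) -> None:
        state, config = load_checkpoint(path)
        saved = config.get("encoder", {})
        mine = self.encoder_cfg.to_dict()
        mismatched = sorted(
            k for k in ("stage_channels", "stage_depths", "attention_heads", "input_size",
                        "dilation_rates", "whdc_reduction_ratio")
            if list(np.atleast_1d(saved.get(k))) != list(np.atleast_1d(mine[k]))
        )
        if mismatched:
            raise ValueError(f"encoder checkpoint incompatible; mismatched fields: {mismatched}")
        self.encoder.load_state_dict(state)


# ----------------------------------------------------------------- losses
def _pair(y, t) -> tuple[Tensor, Tensor]:
    yt = y if isinstance(y, Tensor) else Tensor(np.asarray(y, dtype=np.float64))
    tt = t if isinstance(t, Tensor) else Tensor(np.asarray(t, dtype=np.float64))
    if yt.shape != tt.shape:
        raise ValueError(f"shape mismatch: ground truth {yt.shape} vs prediction {tt.shape}")
    return yt, tt


def _maybe_float(result: Tensor, y, t):
    if isinstance(y, Tensor) or isinstance(t, Tensor):
        return result
    return float(result.data)


def bce_loss(y, t):
    """Pixel-mean binary cross-entropy; predictions clamped to
    [1e-7, 1 - 1e-7] before the logs."""
    yt, tt = _pair(y, t)
    tc = tt.clip(_BCE_EPS, 1.0 - _BCE_EPS)
    loss = -(yt * tc.log() + (1.0 - yt) * (1.0 - tc).log()).mean()
    return _maybe_float(loss, y, t)


def dice_loss(y, t):
    """Soft Dice loss, computed per image and averaged over the batch.

    1 - (2 sum(y t) + s) / (sum(y^2) + sum(t^2) + s), smoothing s = 1e-6,
    so two empty masks score a perfect 0.
    """
    yt, tt = _pair(y, t)
    if yt.ndim <= 2:
        axes = None
        inter = (yt * tt).sum()
        denom = (yt * yt).sum() + (tt * tt).sum()
        loss = 1.0 - (2.0 * inter + _DICE_SMOOTH) / (denom + _DICE_SMOOTH)
    else:
        axes = tuple(range(1, yt.ndim))
        inter = (yt * tt).sum(axis=axes)
        denom = (yt * yt).sum(axis=axes) + (tt * tt).sum(axis=axes)
        loss = (1.0 - (2.0 * inter + _DICE_SMOOTH) / (denom + _DICE_SMOOTH)).mean()
    return _maybe_float(loss, y, t)


def combined_loss(y, t, gamma: float = 0.4):
    """Overall segmentation loss: gamma * BCE + (1 - gamma) * Dice."""
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must be in [0, 1]")
    yt, tt = _pair(y, t)
    loss = gamma * bce_loss(yt, tt) + (1.0 - gamma) * dice_loss(yt, tt)
    return _maybe_float(loss, y, t)


# --------------------------------------------------------------- training
def train_segmentation(
    patchset: dp.PatchSet,
    pretrained_checkpoint,
    cfg: SegConfig,
    encoder_cfg: EncoderConfig,
    out_dir,
    augment_cfg: dp.AugmentConfig | None = None,
) -> tuple[Path, Path]:
    """Supervised training of the segmentation network.

    The encoder starts from ``pretrained_checkpoint`` when given and from
    random initialisation otherwise (the no-pretraining ablation arm).
    Masks are binarised (any instance label > 0 is foreground).  Returns
    (checkpoint_path, loss_log_path).
    """
    if len(patchset) == 0:
        raise ValueError("empty patch set")
    rng = np.random.default_rng(cfg.seed)
    model = SegModel(encoder_cfg, cfg, rng=np.random.default_rng(rng.integers(2**31)))
    if pretrained_checkpoint is not None:
        model.load_encoder_checkpoint(pretrained_checkpoint)

    params = list(model.parameters())
    if cfg.freeze_encoder:
        enc_ids = {id(p) for p in model.encoder.parameters()}
        params = [p for p in params if id(p) not in enc_ids]
    opt = Adam(params, lr=cfg.lr, betas=cfg.betas)

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ckpt_path = out_dir / "segmodel.ckpt"
    log_path = out_dir / "train_loss.csv"

    with open(log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "mean_loss"])
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(patchset))
            losses = []
            model.train()
            for start in range(0, len(order), cfg.batch_size):
                idxs = order[start : start + cfg.batch_size]
                imgs, masks = [], []
                for i in idxs:
                    img, mask = patchset.load(int(i))
                    if augment_cfg is not None:
                        img, mask = dp.augment_pair_geometric(img, mask, augment_cfg, rng)
                    imgs.append(img.transpose(2, 0, 1))
                    masks.append((mask > 0).astype(np.float32)[None])
                x = Tensor(np.stack(imgs).astype(np.float32))
                y = Tensor(np.stack(masks))
                prob = model(x)
                loss = combined_loss(y, prob, cfg.gamma)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            writer.writerow([epoch, float(np.mean(losses))])
            fh.flush()
            save_checkpoint(
                ckpt_path, model,
                {"encoder": encoder_cfg.to_dict(), "seg": dataclasses.asdict(cfg), "stage": "segmentation"},
            )
    return ckpt_path, log_path


def load_seg_model(path) -> SegModel:
    state, config = load_checkpoint(path)
    enc_cfg = EncoderConfig(**config["encoder"])
    seg_kw = config["seg"]
    seg_cfg = SegConfig(**{k: (tuple(v) if isinstance(v, list) else v) for k, v in seg_kw.items()})
    model = SegModel(enc_cfg, seg_cfg, rng=0)
    model.load_state_dict(state)
    return model


# -------------------------------------------------------------- inference
def predict_mask(img: np.ndarray, model: SegModel, threshold: float | None = None) -> np.ndarray:
    """Binary foreground mask: pixel = 1 iff probability >= threshold."""
    if threshold is None:
        threshold = model.seg_cfg.threshold
    size = model.encoder_cfg.input_size
    if img.shape[0] != size or img.shape[1] != size:
        img = dp.resize_image(img, size)
    model.eval()
    prob = model(Tensor(img.transpose(2, 0, 1)[None].astype(np.float32))).data[0, 0]
    return (prob >= threshold).astype(np.uint8)


def write_prediction_overlay(path, img: np.ndarray, pred: np.ndarray, gt: np.ndarray) -> None:
    """RGB error overlay: true positives orange, false positives green,
    false negatives red, true negatives show the input."""
    pred_b = pred > 0
    gt_b = gt > 0
    out = img.copy()
    out[pred_b & gt_b] = (1.0, 0.65, 0.0)
    out[pred_b & ~gt_b] = (0.0, 0.8, 0.0)
    out[~pred_b & gt_b] = (0.9, 0.0, 0.0)
    dp.save_image(path, out)
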