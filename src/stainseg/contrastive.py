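"""Self-supervised contrastive pretraining of the encoder (SimCLR-style).

Each image in a mini-batch of N contributes two stochastically augmented
views; the encoder's pooled bottleneck vector is mapped by a projection
head ``z = W2 relu(W1 v)`` into a 128-dimensional space.  With projections
stored pair-adjacent (views 2k and 2k+1 come from image k), the normalised
temperature-scaled cross entropy (NT-Xent) for an ordered pair (i, j) is

    l(i, j) = -log exp(cos(z_i, z_j)/tau) / sum_{k != i} exp(cos(z_i, z_k)/tau)

and the batch loss averages l over all 2N ordered positive pairs.  The
temperature defaults to 0.07.  The projection head is dropped after
pretraining; only the encoder weights move to the segmentation network.
"""

from __future__ import annotations

import csv
import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import data_pipeline as dp
from .nn import SGD, Linear, Module, Tensor, save_checkpoint, stack
from .sie_encoder import EncoderConfig, SIEEncoder

__all__ = [
    "ContrastiveConfig",
    "ProjectionHead",
    "project",
    "cosine_similarity",
    "ntxent_pair",
    "ntxent_batch",
    "pretrain",
]

logger = logging.getLogger(__name__)


@dataclasses.dataclass
class ContrastiveConfig:
    temperature: float = 0.07
    batch_size: int = 2
    epochs: int = 50
    lr: float = 0.001
    momentum: float = 0.9
    projection_dim: int = 128
    seed: int = 0

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be > 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


class ProjectionHead(Module):
    """Two bias-free linear maps with a ReLU: in_dim -> in_dim -> out_dim."""

    def __init__(self, in_dim: int, out_dim: int = 128, *, rng: np.random.Generator):
        super().__init__()
        self.w1 = Linear(in_dim, in_dim, bias=False, rng=rng)
        self.w2 = Linear(in_dim, out_dim, bias=False, rng=rng)

    def forward(self, v: Tensor) -> Tensor:
        return self.w2(self.w1(v).relu())


def project(bottleneck, head: ProjectionHead):
    """Map a pooled encoder vector (or batch) through the projection head."""
    if isinstance(bottleneck, Tensor):
        return head(bottleneck)
    arr = np.asarray(bottleneck, dtype=np.float64)
    out = head(Tensor(np.atleast_2d(arr))).data
    return out[0] if arr.ndim == 1 else out


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.dot(a, b) / (na * nb))


def _cosine_matrix(z: Tensor) -> Tensor:
    norms = (z * z).sum(axis=1, keepdims=True).sqrt()
    zn = z / norms
    return zn @ zn.transpose(1, 0)


def ntxent_pair(i: int, j: int, projections, temperature: float = 0.07) -> float:
    """NT-Xent loss for ordered positive pair (i, j); the denominator sums
    over every k != i, including the other images' views."""
    z = [np.asarray(p, dtype=np.float64) for p in projections]
    if len(z) < 2:
        raise ValueError("need at least 2 projections")
    if i == j:
        raise ValueError("pair indices must differ")
    sims = np.array([cosine_similarity(z[i], z[k]) for k in range(len(z))])
    logits = sims / temperature
    num = np.exp(logits[j])
    den = sum(np.exp(logits[k]) for k in range(len(z)) if k != i)
    return float(-np.log(num / den))


def _ntxent_batch_t(z: Tensor, temperature: float) -> Tensor:
    """Differentiable batch NT-Xent on pair-adjacent projections (2N, D)."""
    m = z.shape[0]
    if m % 2:
        raise ValueError("projection count must be even (views stored pair-adjacent)")
    n = m // 2
    logits = _cosine_matrix(z) * (1.0 / temperature)
    # mask self-similarity out of each row's denominator
    neg_inf = np.full((m, m), 0.0)
    np.fill_diagonal(neg_inf, -1e9)
    logits = logits + Tensor(neg_inf)
    logsumexp_rows = logits.exp().sum(axis=1).log()
    total = None
    for k in range(n):
        a, b = 2 * k, 2 * k + 1
        for i, j in ((a, b), (b, a)):
            term = logsumexp_rows[i] - logits[i, j]
            total = term if total is None else total + term
    return total * (1.0 / m)


def ntxent_batch(projections, temperature: float = 0.07) -> float:
    """Mean NT-Xent over all 2N ordered positive pairs of a batch."""
    z = Tensor(np.asarray([np.asarray(p, dtype=np.float64) for p in projections]))
    return float(_ntxent_batch_t(z, temperature).data)


def pretrain(
    manifest_path,
    encoder_cfg: EncoderConfig,
    cfg: ContrastiveConfig,
    out_dir,
    augment_cfg: dp.AugmentConfig | None = None,
) -> tuple[Path, Path]:
    """Contrastive pretraining loop over a corpus manifest.

    Returns (checkpoint_path, loss_log_path).  The loss log is a CSV with
    columns epoch, mean_loss; the checkpoint is rewritten at each epoch end
    and stores the encoder parameters plus its config (the projection head
    is intentionally not saved).
    """
    manifest_path = Path(manifest_path)
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    if len(manifest) == 0:
        raise ValueError("empty corpus manifest")
    if cfg.batch_size < 8:
        logger.warning(
            "batch_size=%d gives only %d negatives per anchor; contrastive "
            "gradients will be noisy", cfg.batch_size, 2 * cfg.batch_size - 2,
        )
    if augment_cfg is None:
        augment_cfg = dp.AugmentConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rng = np.random.default_rng(cfg.seed)
    encoder = SIEEncoder(encoder_cfg, rng=np.random.default_rng(rng.integers(2**31)))
    head = ProjectionHead(
        encoder_cfg.stage_channels[4], cfg.projection_dim,
        rng=np.random.default_rng(rng.integers(2**31)),
    )
    opt = SGD(list(encoder.parameters()) + list(head.parameters()), lr=cfg.lr, momentum=cfg.momentum)

    size = encoder_cfg.input_size
    images = []
    for _, row in manifest.iterrows():
        img = dp.load_image(manifest_path.parent / row["image"])
        images.append(dp.resize_image(img, size))

    ckpt_path = out_dir / "encoder.ckpt"
    log_path = out_dir / "pretrain_loss.csv"
    with open(log_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch", "mean_loss"])
        for epoch in range(1, cfg.epochs + 1):
            order = rng.permutation(len(images))
            losses = []
            encoder.train()
            head.train()
            for start in range(0, len(order), cfg.batch_size):
                batch = order[start : start + cfg.batch_size]
                views = []
                for idx in batch:
                    pair = dp.make_contrastive_views(images[idx], augment_cfg, rng)
                    views.append(pair.view_i)
                    views.append(pair.view_j)
                x = Tensor(
                    np.stack([v.transpose(2, 0, 1) for v in views]).astype(np.float32)
                )
                stages = encoder.encode(x)
                z = head(stages.bottleneck)
                loss = _ntxent_batch_t(z, cfg.temperature)
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            writer.writerow([epoch, float(np.mean(losses))])
            fh.flush()
            save_checkpoint(ckpt_path, encoder, {"encoder": encoder_cfg.to_dict(), "stage": "contrastive"})
    return ckpt_path, log_path
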