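"""Image/mask I/O, whole-slide patch extraction, and contrastive view pairs.

The extraction scheme mirrors the training protocol for 1000x1000 H&E
whole-slide images: resize to ``resize_to`` (default 1024), tile into
non-overlapping ``grid_patch`` (512) squares, then draw
``crops_per_patch`` (200) random ``crop_size`` (256) crops per tile, so W
slides yield ``W * (resize_to/grid_patch)**2 * crops_per_patch`` training
pairs.

Coordinates are 0-based row-major; crop windows are half-open
``[r, r+crop) x [c, c+crop)``.  Images live in ``[0, 1]`` float RGB; masks
are non-negative integer instance labels with 0 = background.
"""

from __future__ import annotations

import dataclasses
from collections import OrderedDict
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import resize as _sk_resize

__all__ = [
    "AugmentConfig",
    "PatchExtractionConfig",
    "AugmentedPair",
    "PatchSet",
    "load_image",
    "save_image",
    "load_mask",
    "save_mask",
    "resize_image",
    "resize_mask",
    "grid_patches",
    "random_crops",
    "build_training_set",
    "augment",
    "augment_pair_geometric",
    "make_contrastive_views",
]

PATCHSET_COLUMNS = [
    "crop_image", "crop_mask", "source_image", "tile_row", "tile_col", "crop_row", "crop_col",
]


# --------------------------------------------------------------------- config
@dataclasses.dataclass
class AugmentConfig:
    """Stochastic augmentation policy for contrastive view construction.

    Geometric ops (flips, 90-degree rotations) are label-preserving and can
    be shared with a mask; photometric ops (blur, brightness/contrast,
    color jitter) act on the image only.
    """

    flip_prob: float = 0.5
    rot90_prob: float = 0.5
    blur_prob: float = 0.5
    blur_sigma_range: tuple[float, float] = (0.1, 2.0)
    brightness_contrast_prob: float = 0.2
    color_jitter_prob: float = 0.8
    jitter_strengths: tuple[float, float, float, float] = (0.4, 0.4, 0.4, 0.1)

    def __post_init__(self):
        for name in ("flip_prob", "rot90_prob", "blur_prob", "brightness_contrast_prob", "color_jitter_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")

    @classmethod
    def disabled(cls) -> "AugmentConfig":
        """A no-op policy: both contrastive views equal the input."""
        return cls(
            flip_prob=0.0, rot90_prob=0.0, blur_prob=0.0,
            brightness_contrast_prob=0.0, color_jitter_prob=0.0,
            jitter_strengths=(0.0, 0.0, 0.0, 0.0),
        )


@dataclasses.dataclass
class PatchExtractionConfig:
    resize_to: int = 1024
    grid_patch: int = 512
    crop_size: int = 256
    crops_per_patch: int = 200

    def __post_init__(self):
        if self.resize_to % self.grid_patch:
            raise ValueError(
                f"resize_to ({self.resize_to}) must be divisible by grid_patch ({self.grid_patch})"
            )
        if self.crop_size > self.grid_patch:
            raise ValueError(
                f"crop_size ({self.crop_size}) must not exceed grid_patch ({self.grid_patch})"
            )

    @property
    def tiles_per_wsi(self) -> int:
        return (self.resize_to // self.grid_patch) ** 2


@dataclasses.dataclass
class AugmentedPair:
    view_i: np.ndarray
    view_j: np.ndarray

    def __post_init__(self):
        if self.view_i.shape != self.view_j.shape:
            raise ValueError("contrastive views must share spatial size")


# ------------------------------------------------------------------------ I/O
def load_image(path) -> np.ndarray:
    """Read an 8-bit RGB raster into float RGB in [0, 1]."""
    try:
        arr = iio.imread(path)
    except Exception as exc:  # imageio raises assorted types for bad files
        raise OSError(f"cannot read image {path}: {exc}") from exc
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.shape[-1] == 4:
        arr = arr[..., :3]
    return arr.astype(np.float64) / 255.0


def save_image(path, img: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    u8 = np.rint(np.clip(img, 0.0, 1.0) * 255.0).astype(np.uint8)
    iio.imwrite(path, u8)


def load_mask(path) -> np.ndarray:
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise OSError(f"cannot read mask {path}: {exc}") from exc
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.int64)


def save_mask(path, mask: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if mask.min() < 0 or mask.max() > np.iinfo(np.uint16).max:
        raise ValueError("mask labels must fit in uint16")
    iio.imwrite(path, mask.astype(np.uint16))


# --------------------------------------------------------------------- resize
def resize_image(img: np.ndarray, target: int) -> np.ndarray:
    """Bilinear resize of an RGB image to target x target."""
    if target < 1:
        raise ValueError("target size must be >= 1")
    if img.shape[0] == target and img.shape[1] == target:
        return img.copy()
    out = _sk_resize(img, (target, target), order=1, anti_aliasing=img.shape[0] > target,
                     preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def resize_mask(mask: np.ndarray, target: int) -> np.ndarray:
    """Nearest-neighbour resize of a label mask (no new labels introduced)."""
    if target < 1:
        raise ValueError("target size must be >= 1")
    if mask.shape[0] == target and mask.shape[1] == target:
        return mask.copy()
    out = _sk_resize(mask.astype(np.float64), (target, target), order=0, anti_aliasing=False,
                     preserve_range=True)
    return np.rint(out).astype(mask.dtype)


# -------------------------------------------------------------------- tiling
def grid_patches(img: np.ndarray, patch: int) -> list[np.ndarray]:
    """Non-overlapping row-major tiling; the image side must divide evenly."""
    h, w = img.shape[:2]
    if h % patch or w % patch:
        raise ValueError(f"image size {h}x{w} not divisible by patch size {patch}")
    return [
        img[r : r + patch, c : c + patch].copy()
        for r in range(0, h, patch)
        for c in range(0, w, patch)
    ]


def random_crops(
    img: np.ndarray,
    mask: np.ndarray | None,
    crop: int,
    count: int,
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray | None]]:
    """``count`` aligned random crops; offsets uniform over valid positions."""
    h, w = img.shape[:2]
    if crop > min(h, w):
        raise ValueError(f"crop size {crop} exceeds image size {h}x{w}")
    out = []
    for _ in range(count):
        r = int(rng.integers(0, h - crop + 1))
        c = int(rng.integers(0, w - crop + 1))
        mi = None if mask is None else mask[r : r + crop, c : c + crop].copy()
        out.append((img[r : r + crop, c : c + crop].copy(), mi))
    return out


# ------------------------------------------------------------------ patch set
class PatchSet:
    """Crop index over a manifest of whole-slide image/mask pairs.

    Crops are addressed by (source image, tile, in-tile offset) so the set
    is reproducible from the index alone; pixel data is materialised to PNG
    only when requested, otherwise crops are cut lazily from the (cached)
    resized sources.
    """

    def __init__(
        self,
        index: pd.DataFrame,
        manifest_dir: Path,
        cfg: PatchExtractionConfig,
        sources: pd.DataFrame | None = None,
    ):
        self.index = index.reset_index(drop=True)
        self.manifest_dir = Path(manifest_dir)
        self.cfg = cfg
        self._sources = sources
        self._cache: OrderedDict[str, tuple[np.ndarray, np.ndarray]] = OrderedDict()
        self._cache_cap = 4

    def __len__(self) -> int:
        return len(self.index)

    def _resized_pair(self, image_rel: str) -> tuple[np.ndarray, np.ndarray]:
        if image_rel in self._cache:
            self._cache.move_to_end(image_rel)
            return self._cache[image_rel]
        if self._sources is None:
            raise ValueError("PatchSet has no source manifest; cannot cut lazy crops")
        row = self._sources.loc[image_rel]
        img = resize_image(load_image(self.manifest_dir / image_rel), self.cfg.resize_to)
        mask = resize_mask(load_mask(self.manifest_dir / row["mask"]), self.cfg.resize_to)
        self._cache[image_rel] = (img, mask)
        while len(self._cache) > self._cache_cap:
            self._cache.popitem(last=False)
        return img, mask

    def load(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        row = self.index.iloc[i]
        if row["crop_image"]:
            return (
                load_image(self.manifest_dir / row["crop_image"]),
                load_mask(self.manifest_dir / row["crop_mask"]),
            )
        img, mask = self._resized_pair(row["source_image"])
        g = self.cfg.grid_patch
        r0 = int(row["tile_row"]) * g + int(row["crop_row"])
        c0 = int(row["tile_col"]) * g + int(row["crop_col"])
        s = self.cfg.crop_size
        return img[r0 : r0 + s, c0 : c0 + s].copy(), mask[r0 : r0 + s, c0 : c0 + s].copy()

    def save_index(self, path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.index.to_csv(path, index=False)
        return path

    @classmethod
    def from_index(cls, index_path, manifest_path, cfg: PatchExtractionConfig) -> "PatchSet":
        df = pd.read_csv(index_path, keep_default_na=False)
        manifest_path = Path(manifest_path)
        manifest = pd.read_csv(manifest_path, keep_default_na=False)
        return cls(df, manifest_path.parent, cfg, sources=manifest.set_index("image"))


def build_training_set(
    manifest_path,
    cfg: PatchExtractionConfig,
    rng: np.random.Generator,
    out_dir=None,
    materialize: bool = False,
) -> PatchSet:
    """Run the WSI-to-crop pipeline for every manifest row.

    Emits W * tiles_per_wsi * crops_per_patch crop pairs.  With
    ``materialize=True`` each crop is written to PNG under ``out_dir``;
    otherwise only the index is produced and crops are cut on demand.
    """
    manifest_path = Path(manifest_path)
    manifest_dir = manifest_path.parent
    manifest = pd.read_csv(manifest_path, keep_default_na=False)
    side = cfg.resize_to // cfg.grid_patch

    rows = []
    for w_idx, mrow in manifest.iterrows():
        img_path = manifest_dir / mrow["image"]
        mask_path = manifest_dir / mrow["mask"]
        for p in (img_path, mask_path):
            if not p.exists():
                raise OSError(f"manifest row {w_idx}: missing file {p}")
        tiles = [(tr, tc) for tr in range(side) for tc in range(side)]
        for tr, tc in tiles:
            lim = cfg.grid_patch - cfg.crop_size + 1
            for _ in range(cfg.crops_per_patch):
                rr = int(rng.integers(0, lim))
                cc = int(rng.integers(0, lim))
                rows.append(("", "", mrow["image"], tr, tc, rr, cc))

    index = pd.DataFrame(rows, columns=PATCHSET_COLUMNS)
    ps = PatchSet(index, manifest_dir, cfg, sources=manifest.set_index("image"))

    if materialize:
        if out_dir is None:
            raise ValueError("materialize=True requires out_dir")
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        crop_imgs, crop_masks = [], []
        for i in range(len(ps)):
            img, mask = ps.load(i)
            ip = out_dir / f"crop_{i:06d}.png"
            mp = out_dir / f"crop_{i:06d}_mask.png"
            save_image(ip, img)
            save_mask(mp, mask)
            crop_imgs.append(str(ip.relative_to(manifest_dir)) if ip.is_relative_to(manifest_dir) else str(ip))
            crop_masks.append(str(mp.relative_to(manifest_dir)) if mp.is_relative_to(manifest_dir) else str(mp))
        index["crop_image"] = crop_imgs
        index["crop_mask"] = crop_masks
        ps.index = index
    if out_dir is not None:
        Path(out_dir).mkdir(parents=True, exist_ok=True)
        ps.save_index(Path(out_dir) / "index.csv")
    return ps


# -------------------------------------------------------------- augmentation
def _adjust_saturation(img: np.ndarray, factor: float) -> np.ndarray:
    gray = img @ np.array([0.299, 0.587, 0.114])
    return gray[..., None] + (img - gray[..., None]) * factor


def _shift_hue(img: np.ndarray, delta: float) -> np.ndarray:
    hsv = rgb2hsv(np.clip(img, 0.0, 1.0))
    hsv[..., 0] = (hsv[..., 0] + delta) % 1.0
    return hsv2rgb(hsv)


def sample_geometric(cfg: AugmentConfig, rng: np.random.Generator) -> dict:
    """Draw the label-preserving transform parameters once, for shared use."""
    return {
        "hflip": rng.random() < cfg.flip_prob,
        "vflip": rng.random() < cfg.flip_prob,
        "rot_k": int(rng.integers(1, 4)) if rng.random() < cfg.rot90_prob else 0,
    }


def apply_geometric(arr: np.ndarray, params: dict) -> np.ndarray:
    if params["hflip"]:
        arr = arr[:, ::-1]
    if params["vflip"]:
        arr = arr[::-1, :]
    if params["rot_k"]:
        arr = np.rot90(arr, params["rot_k"], axes=(0, 1))
    return np.ascontiguousarray(arr)


def augment(img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator) -> np.ndarray:
    """One stochastic augmentation pass; output stays in [0, 1]."""
    out = apply_geometric(img, sample_geometric(cfg, rng))
    if rng.random() < cfg.blur_prob:
        sigma = rng.uniform(*cfg.blur_sigma_range)
        out = gaussian_filter(out, sigma=(sigma, sigma, 0))
    if rng.random() < cfg.brightness_contrast_prob:
        fb = 1.0 + rng.uniform(-0.2, 0.2)
        fc = 1.0 + rng.uniform(-0.2, 0.2)
        out = (out * fb - 0.5) * fc + 0.5
    if rng.random() < cfg.color_jitter_prob:
        sb, sc, ss, sh = cfg.jitter_strengths
        if sb:
            out = out * (1.0 + rng.uniform(-sb, sb))
        if sc:
            m = out.mean()
            out = (out - m) * (1.0 + rng.uniform(-sc, sc)) + m
        if ss:
            out = _adjust_saturation(out, 1.0 + rng.uniform(-ss, ss))
        if sh:
            out = _shift_hue(out, rng.uniform(-sh, sh))
    return np.clip(out, 0.0, 1.0)


def augment_pair_geometric(
    img: np.ndarray, mask: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Shared geometric transform for an image and its mask (stays aligned)."""
    params = sample_geometric(cfg, rng)
    return apply_geometric(img, params), apply_geometric(mask, params)


def make_contrastive_views(
    img: np.ndarray, cfg: AugmentConfig, rng: np.random.Generator
) -> AugmentedPair:
    """Two independent stochastic views of one patch for contrastive learning."""
    return AugmentedPair(view_i=augment(img, cfg, rng), view_j=augment(img, cfg, rng))
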