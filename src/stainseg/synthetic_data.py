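"""Synthetic H&E-like nuclei scenes with paired instance masks.

Real H&E whole-slide images vary strongly across laboratories: hematoxylin
renders nuclei in purple-blue shades, eosin renders cytoplasm and stroma in
pinks, and scanners/stain batches shift both.  This module emulates just
enough of that structure to exercise the whole pipeline: filled-ellipse
nuclei of varying size, eccentricity and orientation on a textured pink
background, plus configurable "stain domains" (hue shifts, brightness and
contrast scaling, additive noise) standing in for multi-laboratory color
variation.  Everything is a pure function of (spec, domain, seed).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb, rgb2hsv
from skimage.draw import ellipse as _draw_ellipse

from .data_pipeline import save_image, save_mask

__all__ = [
    "NucleiSceneSpec",
    "StainDomain",
    "generate_patch",
    "apply_stain_domain",
    "generate_corpus",
    "NUCLEUS_BASE_RGB",
    "BACKGROUND_BASE_RGB",
]

# hematoxylin-ish purple for nuclei, eosin-ish pink for background
NUCLEUS_BASE_RGB = (0.35, 0.22, 0.55)
BACKGROUND_BASE_RGB = (0.92, 0.78, 0.86)

# hue band (HSV, in [0,1]) treated as hematoxylin-dominant when applying
# per-stain hue shifts; everything else is treated as eosin-dominant
_HEMATOXYLIN_HUE_BAND = (0.52, 0.88)

_PLACEMENT_ATTEMPTS = 100


@dataclasses.dataclass
class NucleiSceneSpec:
    """Geometry of one synthetic scene."""

    image_size: int = 256
    n_nuclei: int = 12
    radius_range: tuple[float, float] = (8.0, 20.0)
    eccentricity_range: tuple[float, float] = (0.0, 0.7)
    overlap_allowed: bool = True
    background_texture_scale: float = 0.03

    def __post_init__(self):
        if self.image_size < 64:
            raise ValueError(f"image_size must be >= 64, got {self.image_size}")
        if self.n_nuclei < 0:
            raise ValueError("n_nuclei must be >= 0")
        lo, hi = self.radius_range
        if not 0 < lo <= hi:
            raise ValueError(f"invalid radius_range {self.radius_range}")
        if hi >= self.image_size / 4:
            raise ValueError(
                f"max radius {hi} must be < image_size/4 = {self.image_size / 4}"
            )
        elo, ehi = self.eccentricity_range
        if not (0.0 <= elo <= ehi < 1.0):
            raise ValueError(f"eccentricity_range must lie in [0, 1), got {self.eccentricity_range}")


@dataclasses.dataclass
class StainDomain:
    """A laboratory/scanner color condition.

    Hue shifts are in degrees and act separately on hematoxylin-dominant
    (purple) and eosin-dominant (pink) pixels; brightness/contrast are
    multiplicative; noise is additive Gaussian (intensity units in [0,1]).
    The all-identity domain leaves an image bit-identical.
    """

    hematoxylin_hue_shift: float = 0.0
    eosin_hue_shift: float = 0.0
    brightness_scale: float = 1.0
    contrast_scale: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self):
        if self.brightness_scale <= 0 or self.contrast_scale <= 0:
            raise ValueError("brightness_scale and contrast_scale must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    @property
    def is_identity(self) -> bool:
        return (
            self.hematoxylin_hue_shift == 0.0
            and self.eosin_hue_shift == 0.0
            and self.brightness_scale == 1.0
            and self.contrast_scale == 1.0
            and self.noise_sd == 0.0
        )


def _sample_ellipse(spec: NucleiSceneSpec, rng: np.random.Generator):
    a = rng.uniform(*spec.radius_range)  # semi-major axis
    e = rng.uniform(*spec.eccentricity_range)
    b = a * np.sqrt(1.0 - e * e)  # semi-minor axis
    margin = int(np.ceil(a)) + 1
    size = spec.image_size
    r = rng.uniform(margin, size - margin)
    c = rng.uniform(margin, size - margin)
    theta = rng.uniform(0.0, np.pi)
    return r, c, a, b, theta


def generate_patch(spec: NucleiSceneSpec, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Render one scene; returns (RGB image in [0,1], instance mask).

    Mask labels are consecutive ``1..k``; when ``overlap_allowed`` is false,
    each nucleus gets up to 100 placement attempts and is skipped if none
    avoids existing nuclei, so ``k`` may fall short of ``n_nuclei``.
    """
    rng = np.random.default_rng(seed)
    size = spec.image_size
    mask = np.zeros((size, size), dtype=np.int32)

    # background: jittered base pink plus smooth texture
    bg = np.array(BACKGROUND_BASE_RGB) + rng.normal(0.0, 0.015, size=3)
    img = np.ones((size, size, 3)) * bg
    if spec.background_texture_scale > 0:
        tex = gaussian_filter(rng.normal(0.0, 1.0, size=(size, size)), sigma=6.0)
        tex /= max(np.abs(tex).max(), 1e-9)
        img += tex[..., None] * spec.background_texture_scale

    nucleus_base = np.array(NUCLEUS_BASE_RGB) + rng.normal(0.0, 0.02, size=3)
    label = 0
    for _ in range(spec.n_nuclei):
        placed = False
        attempts = 1 if spec.overlap_allowed else _PLACEMENT_ATTEMPTS
        for _ in range(attempts):
            r, c, a, b, theta = _sample_ellipse(spec, rng)
            rr, cc = _draw_ellipse(r, c, a, b, shape=(size, size), rotation=theta)
            if rr.size == 0:
                continue
            if not spec.overlap_allowed and np.any(mask[rr, cc] > 0):
                continue
            placed = True
            break
        if not placed:
            continue
        label += 1
        mask[rr, cc] = label
        color = np.clip(nucleus_base + rng.normal(0.0, 0.025, size=3), 0.0, 1.0)
        # radial shading: slightly darker core, like dense chromatin
        dist = np.sqrt(((rr - r) / max(a, 1e-9)) ** 2 + ((cc - c) / max(b, 1e-9)) ** 2)
        shade = 0.85 + 0.15 * np.clip(dist, 0.0, 1.0)
        img[rr, cc] = color * shade[:, None]

    # compact labels after overwrites (a nucleus can be fully painted over)
    present = np.unique(mask)
    present = present[present > 0]
    if present.size and (present[-1] != present.size or present[0] != 1):
        remap = np.zeros(int(present[-1]) + 1, dtype=mask.dtype)
        remap[present] = np.arange(1, present.size + 1)
        mask = remap[mask]

    return np.clip(img, 0.0, 1.0), mask.astype(np.int32)


def apply_stain_domain(img: np.ndarray, domain: StainDomain, seed: int = 0) -> np.ndarray:
    """Recolor an image into a stain domain; output clipped to [0, 1]."""
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("image values must lie in [0, 1]")
    if domain.is_identity:
        return img.copy()
    out = img.astype(np.float64)
    if domain.hematoxylin_hue_shift or domain.eosin_hue_shift:
        hsv = rgb2hsv(out)
        hue = hsv[..., 0]
        lo, hi = _HEMATOXYLIN_HUE_BAND
        hema = (hue >= lo) & (hue <= hi)
        shift = np.where(hema, domain.hematoxylin_hue_shift, domain.eosin_hue_shift) / 360.0
        hsv[..., 0] = (hue + shift) % 1.0
        out = hsv2rgb(hsv)
    if domain.brightness_scale != 1.0:
        out = out * domain.brightness_scale
    if domain.contrast_scale != 1.0:
        out = (out - 0.5) * domain.contrast_scale + 0.5
    if domain.noise_sd > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, domain.noise_sd, size=out.shape)
    return np.clip(out, 0.0, 1.0)


def generate_corpus(
    n_images: int,
    spec: NucleiSceneSpec,
    domains: list[StainDomain],
    out_dir,
    seed: int,
) -> Path:
    """Write ``n_images`` image/mask PNG pairs cycling through the stain
    domains, plus a ``manifest.csv`` (columns image,mask,domain,seed).

    Re-running with identical arguments reproduces byte-identical files.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if not domains:
        domains = [StainDomain()]
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create corpus directory {out_dir}: {exc}") from exc

    rows = []
    for i in range(n_images):
        img_seed = seed + i
        d_idx = i % len(domains)
        img, mask = generate_patch(spec, img_seed)
        img = apply_stain_domain(img, domains[d_idx], seed=img_seed)
        img_name = f"img_{i:04d}.png"
        mask_name = f"img_{i:04d}_mask.png"
        save_image(out_dir / img_name, img)
        save_mask(out_dir / mask_name, mask)
        rows.append((img_name, mask_name, d_idx, img_seed))

    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows, columns=["image", "mask", "domain", "seed"]).to_csv(manifest, index=False)
    return manifest
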