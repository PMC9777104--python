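"""I/O round trips, the WSI-to-crop extraction law, and augmentation pairs."""

import numpy as np
import pandas as pd
import pytest

from stainseg import data_pipeline as dp
from stainseg import synthetic_data as sd


# ------------------------------------------------------------------- I/O
def test_image_round_trip_bit_identical(tmp_path, rng):
    img = np.rint(rng.random((32, 32, 3)) * 255) / 255.0
    dp.save_image(tmp_path / "x.png", img)
    loaded = dp.load_image(tmp_path / "x.png")
    assert np.array_equal(loaded, img)


def test_mask_round_trip_preserves_large_labels(tmp_path):
    mask = np.zeros((16, 16), dtype=np.int64)
    mask[2:5, 2:5] = 300
    mask[10:12, 10:12] = 65535
    dp.save_mask(tmp_path / "m.png", mask)
    assert np.array_equal(dp.load_mask(tmp_path / "m.png"), mask)


def test_load_non_image_raises_io_error(tmp_path):
    bad = tmp_path / "not_an_image.png"
    bad.write_text("plain text, not a PNG")
    with pytest.raises(OSError):
        dp.load_image(bad)
    with pytest.raises(OSError):
        dp.load_mask(bad)


# ---------------------------------------------------------------- resize
def test_resize_identity_and_constant_preservation(rng):
    img = rng.random((64, 64, 3))
    assert np.array_equal(dp.resize_image(img, 64), img)
    const = np.full((32, 32, 3), 0.37)
    up = dp.resize_image(const, 64)
    assert np.allclose(up, 0.37, atol=1e-12)


def test_resize_mask_introduces_no_new_labels(rng):
    mask = rng.integers(0, 3, size=(40, 40)).astype(np.int32)
    for target in (20, 64):
        out = dp.resize_mask(mask, target)
        assert set(np.unique(out)) <= set(np.unique(mask))
        assert out.shape == (target, target)


# ---------------------------------------------------------------- tiling
def test_grid_patches_counts_and_conservation(rng):
    img = rng.random((64, 64, 3))
    tiles = dp.grid_patches(img, 32)
    assert len(tiles) == 4
    assert np.isclose(sum(t.sum() for t in tiles), img.sum())
    # row-major order: first tile is the top-left block
    assert np.array_equal(tiles[0], img[:32, :32])
    assert np.array_equal(tiles[1], img[:32, 32:])

    single = dp.grid_patches(img, 64)
    assert len(single) == 1 and np.array_equal(single[0], img)

    with pytest.raises(ValueError):
        dp.grid_patches(img, 48)


def test_random_crops_are_aligned_and_reproducible(rng):
    img = rng.random((40, 40, 3))
    mask = (img[..., 0] * 5).astype(np.int32)
    crops1 = dp.random_crops(img, mask, 16, 10, np.random.default_rng(3))
    crops2 = dp.random_crops(img, mask, 16, 10, np.random.default_rng(3))
    assert len(crops1) == 10
    for (i1, m1), (i2, m2) in zip(crops1, crops2):
        assert i1.shape == (16, 16, 3)
        assert np.array_equal(i1, i2) and np.array_equal(m1, m2)
        # alignment: the mask crop is the deterministic function of its image crop
        assert np.array_equal((i1[..., 0] * 5).astype(np.int32), m1)

    full = dp.random_crops(img, mask, 40, 3, np.random.default_rng(0))
    for ci, cm in full:
        assert np.array_equal(ci, img) and np.array_equal(cm, mask)

    with pytest.raises(ValueError):
        dp.random_crops(img, mask, 41, 1, np.random.default_rng(0))


# ------------------------------------------------------------- patch set
@pytest.fixture
def wsi_manifest(tmp_path):
    spec = sd.NucleiSceneSpec(image_size=80, n_nuclei=4, radius_range=(5.0, 10.0))
    return sd.generate_corpus(3, spec, [sd.StainDomain()], tmp_path, seed=2)


def test_patch_count_law(wsi_manifest):
    cfg = dp.PatchExtractionConfig(resize_to=64, grid_patch=32, crop_size=16, crops_per_patch=5)
    ps = dp.build_training_set(wsi_manifest, cfg, np.random.default_rng(0))
    assert len(ps) == 3 * 4 * 5  # W * (resize/grid)^2 * crops
    img, mask = ps.load(0)
    assert img.shape == (16, 16, 3) and mask.shape == (16, 16)


def test_patchset_materialized_equals_lazy(wsi_manifest, tmp_path):
    cfg = dp.PatchExtractionConfig(resize_to=64, grid_patch=32, crop_size=16, crops_per_patch=2)
    lazy = dp.build_training_set(wsi_manifest, cfg, np.random.default_rng(5))
    mat = dp.build_training_set(wsi_manifest, cfg, np.random.default_rng(5),
                                out_dir=tmp_path / "mat", materialize=True)
    assert len(lazy) == len(mat)
    for i in range(len(lazy)):
        li, lm = lazy.load(i)
        mi, mm = mat.load(i)
        # materialised crops go through 8-bit PNG quantisation
        assert np.abs(li - mi).max() <= 1.0 / 255.0 + 1e-12
        assert np.array_equal(lm, mm)


def test_patchset_index_round_trip(wsi_manifest, tmp_path):
    cfg = dp.PatchExtractionConfig(resize_to=64, grid_patch=32, crop_size=16, crops_per_patch=2)
    ps = dp.build_training_set(wsi_manifest, cfg, np.random.default_rng(5), out_dir=tmp_path / "o")
    ps2 = dp.PatchSet.from_index(tmp_path / "o" / "index.csv", wsi_manifest, cfg)
    assert list(ps2.index.columns) == dp.PATCHSET_COLUMNS
    i1, m1 = ps.load(3)
    i2, m2 = ps2.load(3)
    assert np.array_equal(i1, i2) and np.array_equal(m1, m2)


def test_empty_manifest_gives_empty_set(tmp_path):
    mpath = tmp_path / "manifest.csv"
    pd.DataFrame(columns=["image", "mask", "domain", "seed"]).to_csv(mpath, index=False)
    ps = dp.build_training_set(mpath, dp.PatchExtractionConfig(), np.random.default_rng(0))
    assert len(ps) == 0


def test_missing_file_error_names_the_row(tmp_path, wsi_manifest):
    df = pd.read_csv(wsi_manifest)
    df.loc[1, "image"] = "missing.png"
    broken = tmp_path / "broken.csv"
    df.to_csv(broken, index=False)
    with pytest.raises(OSError, match="row 1"):
        dp.build_training_set(broken, dp.PatchExtractionConfig(resize_to=64, grid_patch=32,
                                                               crop_size=16, crops_per_patch=1),
                              np.random.default_rng(0))


def test_extraction_config_validation():
    with pytest.raises(ValueError):
        dp.PatchExtractionConfig(resize_to=1000, grid_patch=512)
    with pytest.raises(ValueError):
        dp.PatchExtractionConfig(crop_size=600, grid_patch=512)


# ----------------------------------------------------------- augmentation
def test_noop_augmentation_returns_input(rng):
    img = rng.random((32, 32, 3))
    pair = dp.make_contrastive_views(img, dp.AugmentConfig.disabled(), rng)
    assert np.array_equal(pair.view_i, img)
    assert np.array_equal(pair.view_j, img)


def test_fixed_seed_reproduces_views(rng):
    img = rng.random((32, 32, 3))
    cfg = dp.AugmentConfig()
    p1 = dp.make_contrastive_views(img, cfg, np.random.default_rng(8))
    p2 = dp.make_contrastive_views(img, cfg, np.random.default_rng(8))
    assert np.array_equal(p1.view_i, p2.view_i) and np.array_equal(p1.view_j, p2.view_j)


def test_flip_only_augmentation_is_an_involution(rng):
    img = rng.random((32, 32, 3))
    cfg = dp.AugmentConfig(flip_prob=1.0, rot90_prob=0.0, blur_prob=0.0,
                           brightness_contrast_prob=0.0, color_jitter_prob=0.0,
                           jitter_strengths=(0, 0, 0, 0))
    once = dp.augment(img, cfg, np.random.default_rng(0))
    assert np.array_equal(once, img[::-1, ::-1])  # both flips applied at p=1
    twice = dp.augment(once, cfg, np.random.default_rng(0))
    assert np.array_equal(twice, img)


def test_augmented_range_stays_in_unit_interval(rng):
    img = rng.random((32, 32, 3))
    cfg = dp.AugmentConfig()
    for seed in range(10):
        out = dp.augment(img, cfg, np.random.default_rng(seed))
        assert out.min() >= 0.0 and out.max() <= 1.0


def test_shared_geometric_transform_keeps_pair_aligned(rng):
    mask = rng.integers(0, 4, size=(24, 24)).astype(np.int32)
    img = np.stack([mask * 0.1] * 3, axis=-1)  # image is a function of the mask
    cfg = dp.AugmentConfig(flip_prob=0.5, rot90_prob=0.5)
    for seed in range(6):
        ai, am = dp.augment_pair_geometric(img, mask, cfg, np.random.default_rng(seed))
        assert np.allclose(ai, np.stack([am * 0.1] * 3, axis=-1))
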