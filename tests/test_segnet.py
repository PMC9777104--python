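"""Attention gate, decoder contract, losses with scalar oracles, training."""

import numpy as np
import pandas as pd
import pytest

from stainseg import data_pipeline as dp
from stainseg.nn import Tensor
from stainseg.segnet import (
    AttentionGate,
    SegConfig,
    SegModel,
    bce_loss,
    combined_loss,
    dice_loss,
    load_seg_model,
    predict_mask,
    train_segmentation,
    write_prediction_overlay,
)


# --------------------------------------------------------- attention gate
def test_gate_coefficients_bounded(rng):
    gate = AttentionGate(8, 16, rng=np.random.default_rng(0))
    skip = Tensor(rng.normal(size=(1, 8, 16, 16)).astype(np.float32))
    gating = Tensor(rng.normal(size=(1, 16, 8, 8)).astype(np.float32))
    out = gate(skip, gating).data
    ratio = out / np.where(skip.data == 0, 1, skip.data)
    assert out.shape == skip.shape
    assert ratio.min() > 0.0 and ratio.max() < 1.0


def test_zero_psi_gives_half_attenuation(rng):
    gate = AttentionGate(4, 4, rng=np.random.default_rng(1))
    gate.psi.weight.data[:] = 0.0
    gate.psi.bias.data[:] = 0.0
    skip = Tensor(rng.normal(size=(2, 4, 8, 8)).astype(np.float32))
    gating = Tensor(rng.normal(size=(2, 4, 4, 4)).astype(np.float32))
    assert np.allclose(gate(skip, gating).data, skip.data * 0.5)


def test_gate_matches_hand_arithmetic_on_scalar_toy():
    gate = AttentionGate(1, 1, inter_ch=1, rng=np.random.default_rng(0))
    ws, wg, bg = 0.7, -0.4, 0.1
    wp, bp = 1.3, -0.2
    gate.w_skip.weight.data[:] = ws
    gate.w_gate.weight.data[:] = wg
    gate.w_gate.bias.data[:] = bg
    gate.psi.weight.data[:] = wp
    gate.psi.bias.data[:] = bp
    skip = np.array([[1.0, 2.0], [3.0, 4.0]]).reshape(1, 1, 2, 2)
    gating = np.array([[0.5]]).reshape(1, 1, 1, 1)
    pre = np.maximum(ws * skip + (wg * 0.5 + bg), 0.0)
    coeff = 1.0 / (1.0 + np.exp(-(wp * pre + bp)))
    assert np.allclose(gate(Tensor(skip), Tensor(gating)).data, skip * coeff)


def test_gate_rejects_larger_gating_signal(rng):
    gate = AttentionGate(4, 4, rng=np.random.default_rng(0))
    with pytest.raises(ValueError):
        gate(Tensor(np.zeros((1, 4, 4, 4))), Tensor(np.zeros((1, 4, 8, 8))))


# ----------------------------------------------------------------- decoder
def test_decoder_restores_input_resolution_in_unit_interval(tiny_cfg_64, rng):
    model = SegModel(tiny_cfg_64, rng=0).eval()
    x = Tensor(rng.random((2, 3, 64, 64)).astype(np.float32))
    prob = model(x)
    assert prob.shape == (2, 1, 64, 64)
    assert prob.data.min() > 0.0 and prob.data.max() < 1.0
    assert np.array_equal(prob.data, model(x).data)  # deterministic in eval


# ------------------------------------------------------------------ losses
def test_bce_closed_forms():
    y = np.array([[1.0]])
    assert np.isclose(bce_loss(y, np.array([[0.5]])), np.log(2.0))
    assert np.isclose(bce_loss(y, np.array([[1e-7]])), -np.log(1e-7))
    assert np.isclose(bce_loss(y, np.array([[2.0]])), -np.log(1 - 1e-7))  # clamp ceiling
    match = np.array([[1.0, 0.0], [0.0, 1.0]])
    assert bce_loss(match, match) < 1e-5


def test_dice_closed_forms():
    y = np.zeros((4, 4))
    y[0, 0] = y[0, 1] = 1.0
    t = np.zeros((4, 4))
    t[0, 0] = 1.0
    assert np.isclose(dice_loss(y, t), 1.0 / 3.0, atol=1e-5)
    assert dice_loss(y, y) < 1e-5
    disjoint = np.zeros((4, 4))
    disjoint[3, 3] = 1.0
    assert dice_loss(y, disjoint) > 1.0 - 1e-5
    assert dice_loss(np.zeros((4, 4)), np.zeros((4, 4))) < 1e-6  # both empty: perfect


def test_combined_loss_endpoints_and_example():
    y = np.array([[1.0, 0.0]])
    t = np.array([[0.7, 0.2]])
    assert np.isclose(combined_loss(y, t, 1.0), bce_loss(y, t))
    assert np.isclose(combined_loss(y, t, 0.0), dice_loss(y, t))
    got = combined_loss(y, t, 0.4)
    assert np.isclose(got, 0.4 * bce_loss(y, t) + 0.6 * dice_loss(y, t))


def test_losses_match_scalar_loop_oracles(rng):
    def bce_oracle(y, t):
        eps = 1e-7
        total = 0.0
        for yy, tt in zip(y.ravel(), t.ravel()):
            tc = min(max(tt, eps), 1 - eps)
            total += -(yy * np.log(tc) + (1 - yy) * np.log(1 - tc))
        return total / y.size

    def dice_oracle(y, t):
        s = 1e-6
        inter = sum(a * b for a, b in zip(y.ravel(), t.ravel()))
        denom = sum(a * a for a in y.ravel()) + sum(b * b for b in t.ravel())
        return 1 - (2 * inter + s) / (denom + s)

    for _ in range(30):
        y = (rng.random((8, 8)) > 0.5).astype(float)
        t = rng.random((8, 8))
        assert abs(bce_loss(y, t) - bce_oracle(y, t)) < 1e-6
        assert abs(dice_loss(y, t) - dice_oracle(y, t)) < 1e-6
        g = float(rng.random())
        expect = g * bce_oracle(y, t) + (1 - g) * dice_oracle(y, t)
        assert abs(combined_loss(y, t, g) - expect) < 1e-6


def test_combined_loss_monotone_in_gamma(rng):
    y = (rng.random((8, 8)) > 0.5).astype(float)
    t = rng.random((8, 8)) * 0.98 + 0.01
    b, d = bce_loss(y, t), dice_loss(y, t)
    gammas = np.linspace(0, 1, 5)
    vals = [combined_loss(y, t, g) for g in gammas]
    diffs = np.diff(vals)
    assert np.all(diffs > 0) if b > d else np.all(diffs < 0)


def test_loss_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        bce_loss(np.zeros((2, 2)), np.zeros((3, 3)))
    with pytest.raises(ValueError):
        dice_loss(np.zeros((2, 2)), np.zeros((3, 3)))


def test_seg_config_validation():
    with pytest.raises(ValueError):
        SegConfig(gamma=1.5)
    with pytest.raises(ValueError):
        SegConfig(threshold=0.0)


# ---------------------------------------------------------------- training
@pytest.fixture(scope="module")
def tiny_patchset(tmp_path_factory):
    from stainseg import synthetic_data as sd

    out = tmp_path_factory.mktemp("seg_data")
    spec = sd.NucleiSceneSpec(image_size=64, n_nuclei=3, radius_range=(7.0, 12.0),
                              overlap_allowed=False, background_texture_scale=0.02)
    manifest = sd.generate_corpus(8, spec, [sd.StainDomain()], out, seed=5)
    cfg = dp.PatchExtractionConfig(resize_to=64, grid_patch=64, crop_size=64, crops_per_patch=2)
    return dp.build_training_set(manifest, cfg, np.random.default_rng(0))


def test_training_plumbing_and_loss_log(tmp_path, tiny_patchset, tiny_cfg_64):
    cfg = SegConfig(epochs=3, batch_size=4, seed=0, lr=2e-3)
    ckpt, log = train_segmentation(tiny_patchset, None, cfg, tiny_cfg_64, tmp_path)
    df = pd.read_csv(log)
    assert list(df["epoch"]) == [1, 2, 3]
    model = load_seg_model(ckpt)
    assert model.encoder_cfg.input_size == 64


def test_training_loss_decreases_on_easy_data(tmp_path, tiny_patchset, tiny_cfg_64):
    cfg = SegConfig(epochs=6, batch_size=4, seed=0, lr=2e-3)
    _, log = train_segmentation(tiny_patchset, None, cfg, tiny_cfg_64, tmp_path)
    df = pd.read_csv(log)
    assert df["mean_loss"].iloc[-1] < df["mean_loss"].iloc[0]


def test_pretrained_and_random_initialisation_differ(tmp_path, tiny_patchset, tiny_cfg_64,
                                                     small_corpus):
    from stainseg.contrastive import ContrastiveConfig, pretrain

    ckpt, _ = pretrain(small_corpus, tiny_cfg_64,
                       ContrastiveConfig(epochs=1, batch_size=2, seed=0), tmp_path / "pre")
    cfg = SegConfig(epochs=1, batch_size=4, seed=0)
    with_pre, _ = train_segmentation(tiny_patchset, ckpt, cfg, tiny_cfg_64, tmp_path / "a")
    without, _ = train_segmentation(tiny_patchset, None, cfg, tiny_cfg_64, tmp_path / "b")
    m1 = load_seg_model(with_pre)
    m2 = load_seg_model(without)
    diffs = [not np.array_equal(p.data, q.data)
             for p, q in zip(m1.encoder.parameters(), m2.encoder.parameters())]
    assert any(diffs)


def test_incompatible_checkpoint_names_mismatched_fields(tmp_path, tiny_cfg_64, small_corpus):
    from stainseg.contrastive import ContrastiveConfig, pretrain
    from stainseg.sie_encoder import EncoderConfig

    ckpt, _ = pretrain(small_corpus, tiny_cfg_64,
                       ContrastiveConfig(epochs=1, batch_size=2, seed=0), tmp_path)
    other = EncoderConfig.from_preset("tiny", input_size=128)
    model = SegModel(other, rng=0)
    with pytest.raises(ValueError, match="input_size"):
        model.load_encoder_checkpoint(ckpt)


def test_freeze_encoder_keeps_encoder_parameters_fixed(tmp_path, tiny_patchset, tiny_cfg_64):
    cfg = SegConfig(epochs=1, batch_size=4, seed=0, freeze_encoder=True)
    ckpt, _ = train_segmentation(tiny_patchset, None, cfg, tiny_cfg_64, tmp_path)
    model = load_seg_model(ckpt)
    reference = SegModel(tiny_cfg_64, cfg, rng=np.random.default_rng(
        np.random.default_rng(cfg.seed).integers(2**31)))
    for (n1, p), (n2, q) in zip(model.encoder.named_parameters(),
                                reference.encoder.named_parameters()):
        assert n1 == n2
        assert np.allclose(p.data, q.data), f"encoder parameter {n1} moved while frozen"


# --------------------------------------------------------------- inference
def test_threshold_rules(tiny_cfg_64):
    model = SegModel(tiny_cfg_64, rng=0)

    class Stub:
        seg_cfg = model.seg_cfg
        encoder_cfg = model.encoder_cfg

        def __init__(self, value):
            self.value = value

        def eval(self):
            return self

        def __call__(self, x):
            return Tensor(np.full((1, 1, 64, 64), self.value))

    img = np.zeros((64, 64, 3))
    assert predict_mask(img, Stub(0.4)).sum() == 0
    assert predict_mask(img, Stub(0.5)).sum() == 64 * 64  # >= convention at the boundary
    assert predict_mask(img, Stub(0.1), threshold=0.0).sum() == 64 * 64


def test_prediction_overlay_colors(tmp_path):
    img = np.full((4, 4, 3), 0.5)
    pred = np.zeros((4, 4), dtype=np.uint8)
    gt = np.zeros((4, 4), dtype=np.uint8)
    pred[0, 0] = gt[0, 0] = 1   # TP -> orange
    pred[1, 1] = 1              # FP -> green
    gt[2, 2] = 1                # FN -> red
    write_prediction_overlay(tmp_path / "o.png", img, pred, gt)
    out = dp.load_image(tmp_path / "o.png")
    assert out[0, 0, 0] > 0.9 and out[0, 0, 2] < 0.1          # orange-ish
    assert out[1, 1, 1] > 0.6 and out[1, 1, 0] < 0.1          # green
    assert out[2, 2, 0] > 0.8 and out[2, 2, 1] < 0.1          # red
    assert np.allclose(out[3, 3], 0.5, atol=0.01)             # TN untouched
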