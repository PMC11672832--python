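"""Model assembly: variants, numbering, checkpoints, NMS, augmentation."""

import io

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from bcsyolo import nn
from bcsyolo.assembly import (ModelConfig, TrainConfig, AugmentConfig,
                              build_model, save_checkpoint, load_checkpoint,
                              nms, box_iou_xyxy, augment_sample, lr_at_epoch,
                              VARIANT_ALIASES)
from bcsyolo.head import Detection
from bcsyolo.nn import Tensor

TINY = dict(scale="n", num_classes=5, width_mult=0.125, input_size=64)


def _tiny_model(seed=0, **kw):
    cfg = ModelConfig(**{**TINY, **kw})
    return build_model(cfg, seed=seed)


# --------------------------------------------------------------------------
# construction / numbering
# --------------------------------------------------------------------------

def test_all_ablation_variants_constructible_and_ordered():
    """All four study variants build from config alone; parameter counts
    are strictly ordered: shared head < EMA variant, star < baseline."""
    counts = {}
    for name in VARIANT_ALIASES:
        cfg = ModelConfig.from_variant(name, scale="n", num_classes=5)
        counts[name] = build_model(cfg).num_parameters()
    assert counts["star"] < counts["baseline"]
    assert counts["bcs"] < counts["star-ema"]
    assert counts["star-ema"] < counts["baseline"]


def test_layer_numbering_stable_across_builds():
    a = _tiny_model(seed=0).numbering()
    b = _tiny_model(seed=99).numbering()
    assert a == b
    assert len(a) == 23
    for idx in (12, 15, 18, 21):
        assert a[idx] == "C2f"


def test_distill_sites_hookable():
    m = _tiny_model()
    m.eval()
    x = Tensor(np.zeros((1, 3, 64, 64), dtype=np.float32))
    with nn.no_grad():
        _, feats = m(x, capture=[12, 15, 18, 21])
    assert sorted(feats) == [12, 15, 18, 21]
    # P4, P3, P4, P5 spatial sizes at 64 input
    assert feats[15].shape[2:] == (8, 8)
    assert feats[18].shape[2:] == (4, 4)
    assert feats[21].shape[2:] == (2, 2)
    assert feats[12].shape[2:] == (4, 4)


@pytest.mark.parametrize("size", [64, 96, 160])
def test_forward_grid_sizes_scale_with_input(size):
    m = _tiny_model(input_size=size)
    m.eval()
    with nn.no_grad():
        raw = m(Tensor(np.zeros((1, 3, size, size), dtype=np.float32)))
    for lvl, stride in enumerate((8, 16, 32)):
        g = size // stride
        assert raw.reg[lvl].shape[2:] == (g, g)
        assert raw.cls[lvl].shape == (1, 5, g, g)


def test_full_model_grids_at_640():
    """At the native 640 input the three levels produce 80/40/20 grids."""
    cfg = ModelConfig(scale="n", num_classes=5,
                      block_variant="c2f_baseline",
                      head_variant="baseline_decoupled")
    m = build_model(cfg)
    m.eval()
    with nn.no_grad():
        raw = m(Tensor(np.zeros((1, 3, 640, 640), dtype=np.float32)))
    assert raw.cls[0].shape[2:] == (80, 80)
    assert raw.cls[1].shape[2:] == (40, 40)
    assert raw.cls[2].shape[2:] == (20, 20)


def test_unknown_variant_rejected():
    with pytest.raises(ValueError):
        ModelConfig(scale="n", block_variant="c3x")
    with pytest.raises(ValueError):
        ModelConfig.from_variant("nope")
    with pytest.raises(ValueError):
        ModelConfig(scale="n", input_size=100)


# --------------------------------------------------------------------------
# checkpoints
# --------------------------------------------------------------------------

def test_checkpoint_roundtrip_bit_identical_forward():
    m = _tiny_model(seed=4)
    buf = io.BytesIO()
    save_checkpoint(m, buf, precision="single")
    buf.seek(0)
    m2 = load_checkpoint(buf)
    x = Tensor(np.random.default_rng(0).normal(size=(1, 3, 64, 64))
               .astype(np.float32))
    m.eval()
    m2.eval()
    with nn.no_grad():
        a = m(x)
        b = m2(x)
    for lvl in range(3):
        assert np.array_equal(a.reg[lvl].data, b.reg[lvl].data)
        assert np.array_equal(a.cls[lvl].data, b.cls[lvl].data)


def test_checkpoint_preserves_config():
    m = _tiny_model(seed=1)
    buf = io.BytesIO()
    save_checkpoint(m, buf)
    buf.seek(0)
    m2 = load_checkpoint(buf)
    assert m2.config == m.config
    assert m2.numbering() == m.numbering()


def test_half_checkpoint_roughly_half_of_single():
    m = _tiny_model()
    bufs = {}
    for prec in ("half", "single"):
        b = io.BytesIO()
        save_checkpoint(m, b, precision=prec)
        bufs[prec] = b.getbuffer().nbytes
    assert bufs["half"] < 0.62 * bufs["single"]


# --------------------------------------------------------------------------
# NMS
# --------------------------------------------------------------------------

def _det(cls, conf, box):
    return Detection(cls, conf, np.asarray(box, dtype=np.float64))


def test_nms_identical_boxes_keeps_highest_confidence():
    dets = [_det(0, 0.9, [0, 0, 10, 10]), _det(0, 0.8, [0, 0, 10, 10])]
    out = nms(dets, 0.7)
    assert len(out) == 1 and out[0].confidence == 0.9


def test_nms_disjoint_boxes_all_survive():
    dets = [_det(0, 0.9, [0, 0, 10, 10]), _det(0, 0.8, [20, 20, 30, 30]),
            _det(1, 0.7, [0, 0, 10, 10])]
    assert len(nms(dets, 0.5)) == 3


def test_nms_cross_class_never_suppresses():
    dets = [_det(0, 0.9, [0, 0, 10, 10]), _det(1, 0.2, [0, 0, 10, 10])]
    assert len(nms(dets, 0.3)) == 2


def _nms_oracle(dets, thr):
    """Reference greedy suppression written independently with explicit
    loops over a sorted copy."""
    order = sorted(range(len(dets)), key=lambda i: (-dets[i].confidence, i))
    kept = []
    for i in order:
        ok = True
        for j in kept:
            if dets[j].class_id == dets[i].class_id and \
                    box_iou_xyxy(dets[i].box, dets[j].box) > thr:
                ok = False
                break
        if ok:
            kept.append(i)
    return sorted(kept)


@settings(deadline=None, max_examples=40)
@given(st.integers(0, 2**32 - 1), st.floats(0.2, 0.8))
def test_nms_matches_exhaustive_oracle(seed, thr):
    rng = np.random.default_rng(seed)
    dets = []
    for _ in range(20):
        x1, y1 = rng.uniform(0, 60, 2)
        w, h = rng.uniform(5, 40, 2)
        dets.append(_det(int(rng.integers(0, 3)),
                         float(np.round(rng.uniform(0.05, 1.0), 3)),
                         [x1, y1, x1 + w, y1 + h]))
    got = nms(dets, thr)
    expected = [dets[i] for i in _nms_oracle(dets, thr)]
    assert [id(d) for d in got] == [id(d) for d in expected]
    # surviving same-class pairs overlap at most at the threshold
    for a in got:
        for b in got:
            if a is not b and a.class_id == b.class_id:
                assert box_iou_xyxy(a.box, b.box) <= thr + 1e-9


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

def _sample_image(rng):
    img = rng.uniform(0.2, 0.8, size=(48, 64, 3)).astype(np.float32)
    boxes = np.array([[1, 0.5, 0.4, 0.3, 0.25],
                      [3, 0.25, 0.7, 0.2, 0.2]])
    return img, boxes


def test_augment_identity_when_disabled():
    rng = np.random.default_rng(0)
    img, boxes = _sample_image(rng)
    aug = AugmentConfig(hsv_h=0, hsv_s=0, hsv_v=0, translate=0, scale=0,
                        flipud=0, fliplr=0)
    out_img, out_boxes = augment_sample(img, boxes, aug,
                                        np.random.default_rng(1))
    assert np.allclose(out_img, img)
    assert np.allclose(out_boxes, boxes)


def test_augment_horizontal_flip_maps_cx():
    rng = np.random.default_rng(0)
    img, boxes = _sample_image(rng)
    aug = AugmentConfig(hsv_h=0, hsv_s=0, hsv_v=0, translate=0, scale=0,
                        flipud=0, fliplr=1.0)
    out_img, out_boxes = augment_sample(img, boxes, aug,
                                        np.random.default_rng(1))
    assert np.allclose(out_img, img[:, ::-1])
    assert np.allclose(out_boxes[:, 1], 1.0 - boxes[:, 1], atol=1e-9)
    assert np.allclose(out_boxes[:, 3], boxes[:, 3], atol=1e-9)


def test_augment_vertical_flip_maps_cy():
    rng = np.random.default_rng(0)
    img, boxes = _sample_image(rng)
    aug = AugmentConfig(hsv_h=0, hsv_s=0, hsv_v=0, translate=0, scale=0,
                        flipud=1.0, fliplr=0)
    _, out_boxes = augment_sample(img, boxes, aug, np.random.default_rng(1))
    assert np.allclose(out_boxes[:, 2], 1.0 - boxes[:, 2], atol=1e-9)


def test_augment_deterministic_given_seed():
    rng = np.random.default_rng(3)
    img, boxes = _sample_image(rng)
    aug = AugmentConfig()
    a_img, a_boxes = augment_sample(img, boxes, aug,
                                    np.random.default_rng(77))
    b_img, b_boxes = augment_sample(img, boxes, aug,
                                    np.random.default_rng(77))
    assert np.array_equal(a_img, b_img)
    assert np.array_equal(a_boxes, b_boxes)


@settings(deadline=None, max_examples=20)
@given(st.integers(0, 2**32 - 1))
def test_augment_boxes_stay_normalized(seed):
    rng = np.random.default_rng(seed)
    img, boxes = _sample_image(rng)
    _, out = augment_sample(img, boxes, AugmentConfig(),
                            np.random.default_rng(seed))
    if len(out):
        x1 = out[:, 1] - out[:, 3] / 2
        y1 = out[:, 2] - out[:, 4] / 2
        x2 = out[:, 1] + out[:, 3] / 2
        y2 = out[:, 2] + out[:, 4] / 2
        assert np.all(x1 >= -1e-9) and np.all(y1 >= -1e-9)
        assert np.all(x2 <= 1 + 1e-9) and np.all(y2 <= 1 + 1e-9)


# --------------------------------------------------------------------------
# schedules / config validation
# --------------------------------------------------------------------------

def test_learning_rate_starts_at_configured_value():
    cfg = TrainConfig(epochs=100)
    assert lr_at_epoch(cfg, 0) == pytest.approx(0.01)
    assert lr_at_epoch(cfg, 99) == pytest.approx(0.01 * cfg.lrf)
    assert lr_at_epoch(cfg, 50) < lr_at_epoch(cfg, 0)


def test_train_config_defaults_match_study_settings():
    cfg = TrainConfig()
    assert (cfg.epochs, cfg.batch, cfg.workers, cfg.input_size) \
        == (100, 16, 4, 640)
    assert cfg.optimizer == "sgd" and cfg.lr0 == 0.01
    a = cfg.augment
    assert (a.hsv_h, a.hsv_s, a.hsv_v) == (0.015, 0.7, 0.4)
    assert (a.degrees, a.translate, a.scale, a.shear) == (0.0, 0.1, 0.5, 0.0)
    assert (a.flipud, a.fliplr) == (0.5, 0.5)
    assert cfg.nms_iou == 0.7


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(nms_iou=1.5)
    with pytest.raises(ValueError):
        TrainConfig(augment=AugmentConfig(fliplr=1.4))
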