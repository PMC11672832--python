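"""Shared fixtures.

Heavy artifacts (synthetic datasets, short training runs, a distillation
loop) are session-scoped so the end-to-end checks and the unit tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from bcsyolo import (SynthConfig, generate_dataset, ModelConfig, build_model,
                     TrainConfig, train)

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from bcsyolo.data import YoloDataset, letterbox, boxes_to_letterbox

SMALL_IMAGE_SIZE = (324, 180)      # scaled-down render keeping 1297:720 aspect


@pytest.fixture(scope="session")
def tiny_dataset(tmp_path_factory):
    """30-image dataset (6 per class) at reduced render size."""
    out = tmp_path_factory.mktemp("tiny_ds")
    cfg = SynthConfig(n_per_class=(6,) * 5, image_size=SMALL_IMAGE_SIZE,
                      seed=11)
    manifest = generate_dataset(cfg, out)
    return {"dir": out, "cfg": cfg, "manifest": manifest,
            "yaml": out / "dataset.yaml"}


@pytest.fixture(scope="session")
def smoke_dataset(tmp_path_factory):
    """Seeded 200-image dataset (40 per class) for end-to-end smoke runs."""
    out = tmp_path_factory.mktemp("smoke_ds")
    cfg = SynthConfig(n_per_class=(40,) * 5, image_size=SMALL_IMAGE_SIZE,
                      seed=5)
    manifest = generate_dataset(cfg, out)
    return {"dir": out, "cfg": cfg, "manifest": manifest,
            "yaml": out / "dataset.yaml"}


@pytest.fixture(scope="session")
def smoke_train_run(smoke_dataset):
    """5-epoch training of the full BCS variant on the 200-image dataset
    at reduced input resolution; returns (model, per-epoch loss log)."""
    ds = YoloDataset(smoke_dataset["yaml"], "train")
    cfg = ModelConfig(scale="n", num_classes=5,
                      block_variant="c2f_star_ema", head_variant="ssldh",
                      input_size=96)
    model = build_model(cfg, seed=0)
    tc = TrainConfig(epochs=5, batch=16, input_size=96, seed=0)
    log = train(model, ds, tc, augment=False)
    return model, log


@pytest.fixture(scope="session")
def class_model_run(tmp_path_factory):
    """2-epoch smoke training on a larger dataset (100 per class) used
    for the class-distinguishability check; returns (model, val set)."""
    out = tmp_path_factory.mktemp("dist_ds")
    cfg = SynthConfig(n_per_class=(100,) * 5, image_size=SMALL_IMAGE_SIZE,
                      seed=7)
    generate_dataset(cfg, out)
    ds = YoloDataset(out / "dataset.yaml", "train")
    val = YoloDataset(out / "dataset.yaml", "val")
    mcfg = ModelConfig(scale="n", num_classes=5,
                       block_variant="c2f_star_ema", head_variant="ssldh",
                       input_size=96)
    model = build_model(mcfg, seed=0)
    tc = TrainConfig(epochs=2, batch=8, input_size=96, seed=0)
    log = train(model, ds, tc, augment=False)
    return model, val, log


def make_batch(dataset, indices, input_size):
    """Letterboxed (images, boxes) batch from a YoloDataset."""
    imgs, boxes = [], []
    for i in indices:
        img, b = dataset[i]
        canvas, sc, pad = letterbox(img, input_size)
        lb = boxes_to_letterbox(b, (img.shape[1], img.shape[0]),
                                input_size, sc, pad)
        imgs.append(canvas.transpose(2, 0, 1))
        boxes.append(lb)
    return np.stack(imgs), boxes


@pytest.fixture(scope="session")
def distill_run(tiny_dataset):
    """50 distillation steps on a fixed batch; returns the per-step
    loss-component records."""
    from bcsyolo import nn
    from bcsyolo.distill import DistillConfig, Distiller, distill_step

    ds = YoloDataset(tiny_dataset["yaml"], "train")
    batch = make_batch(ds, range(4), 64)
    mcfg = ModelConfig(scale="n", num_classes=5,
                       block_variant="c2f_star_ema", head_variant="ssldh",
                       input_size=64)
    teacher = build_model(mcfg, seed=1)
    student = build_model(mcfg, seed=2)
    # large distillation weight so the CWD term dominates the composite
    # objective: its descent is the observable of this smoke run
    cfg = DistillConfig(loss_weight=500.0)
    distiller = Distiller(teacher, student, cfg)
    opt = nn.SGD(distiller.trainable_parameters(), lr=1e-4, momentum=0.0,
                 weight_decay=0.0)
    teacher_state_before = {k: v.copy()
                            for k, v in teacher.state_dict().items()}
    records = [distill_step(batch, teacher, student, cfg,
                            distiller=distiller, optimizer=opt)
               for _ in range(50)]
    return {"records": records, "teacher": teacher, "student": student,
            "teacher_state_before": teacher_state_before, "batch": batch,
            "config": mcfg, "distill_config": cfg}
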