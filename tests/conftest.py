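"""Shared fixtures: tiny phantoms and a lightly pretrained tiny encoder.

Everything is generated programmatically and seeded; session scope keeps
the expensive pieces (phantom volumes, pretraining) to one build each.
"""
from __future__ import annotations

import numpy as np
import pytest

from maefunet.mae import MAEModel, ViTConfig, model_from_checkpoint, pretrain
from maefunet.phantom import PhantomSpec, make_phantom_volume, render_sequence
from maefunet.volume_io import PreprocessConfig, Volume, extract_slices, StridePlan


@pytest.fixture(scope="session")
def phantom_spec() -> PhantomSpec:
    return PhantomSpec(grid_size=64)


@pytest.fixture(scope="session")
def phantom(phantom_spec):
    """(labels, mask, spacing) for one fixed subject."""
    return make_phantom_volume(phantom_spec, subject_seed=7)


@pytest.fixture(scope="session")
def phantom_t1(phantom, phantom_spec):
    labels, _, spacing = phantom
    return Volume(
        render_sequence(labels, "pseudo_t1", phantom_spec, noise_seed=7), spacing
    )


@pytest.fixture(scope="session")
def brain_slices(phantom, phantom_t1, phantom_spec):
    """Preprocessed 32x32 (image, mask, labels) slices of the fixed subject."""
    labels, mask, spacing = phantom
    cfg = PreprocessConfig(target_size=(32, 32))
    return extract_slices(
        phantom_t1,
        StridePlan(stride=4, axes=(2,)),
        cfg,
        mask_volume=Volume(mask, spacing),
        label_volume=Volume(mask, spacing),
        volume_id="fixture-7",
    )


@pytest.fixture(scope="session")
def tiny_vit_cfg() -> ViTConfig:
    return ViTConfig.tiny(32)


@pytest.fixture(scope="session")
def tiny_encoder(brain_slices, tiny_vit_cfg) -> MAEModel:
    """A briefly pretrained, frozen tiny encoder on 32x32 phantom slices."""
    ckpt = pretrain(brain_slices, tiny_vit_cfg, seed=0, steps=30, batch_size=8)
    enc = model_from_checkpoint(ckpt)
    enc.freeze()
    return enc
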