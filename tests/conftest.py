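"""Shared fixtures: tiny synthetic corpora and desk-scale models."""

import numpy as np
import pytest

from vesselshot import (FewShotSegmenter, ModelConfig, PatchGrid,
                        SyntheticSpec, generate_library)


@pytest.fixture(scope="session")
def small_spec():
    """A small corpus: 6 classes of 112x112 images."""
    return SyntheticSpec(n_classes=6, image_size=112, seed=42)


@pytest.fixture(scope="session")
def small_library(small_spec):
    """6 classes x 4 members of 64x64 patches (stride 48 on 112px images)."""
    grid = PatchGrid.for_extent((112, 112), template=64, stride=48)
    return generate_library(small_spec, grid)


@pytest.fixture(scope="session")
def tiny_model():
    """Upgraded variant at 1/16 width for fast forward passes."""
    return FewShotSegmenter(ModelConfig(channel_scale=0.0625), seed=0)


@pytest.fixture(scope="session")
def tiny_baseline():
    return FewShotSegmenter(
        ModelConfig(channel_scale=0.0625, variant="baseline"), seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
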