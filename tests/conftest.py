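"""Shared fixtures: a small labeled fixture corpus and a trained patch model.

The trained model is session-scoped because training even the reduced
network takes tens of seconds; every test that needs a working classifier
shares it.
"""

from __future__ import annotations

import numpy as np
import pytest

from coralrhythm.annotation import RegionTag, build_patch_dataset, sample_region_pixels
from coralrhythm.fixtures import SceneSpec, generate_colony_image, scene_for_coverage
from coralrhythm.imaging import hsv_red_mask, median_filter_mask
from coralrhythm.patchcnn import CnnSpec, TrainConfig, build_model, train


@pytest.fixture(scope="session")
def fixture_corpus():
    """Six fixture frames with tag rectangles, masks, and a patch dataset."""
    labels, images, scenes = [], {}, {}
    rng = np.random.default_rng(0)
    for i in range(6):
        spec = scene_for_coverage(bloated_pct=40 + 5 * i, semi_pct=20, seed=i)
        img, truth = generate_colony_image(spec)
        iid = f"f{i}"
        images[iid] = img
        scenes[iid] = (spec, truth)
        mask = median_filter_mask(hsv_red_mask(img))
        for rect, status in spec.regions:
            tag = RegionTag(iid, (0, rect[1], 256, rect[3]), status)
            labels.extend(sample_region_pixels(tag, mask, 60, 20, rng))
    patchset = build_patch_dataset(labels, images)
    return {"labels": labels, "images": images, "scenes": scenes, "patchset": patchset}


@pytest.fixture(scope="session")
def trained_model(fixture_corpus):
    """Reduced-width patch classifier trained on the fixture corpus."""
    model = build_model(CnnSpec.reduced(), seed=0)
    train(model, fixture_corpus["patchset"],
          TrainConfig(epochs=15, batch_size=64, learning_rate=1e-3, seed=0))
    return model


@pytest.fixture()
def two_band_scene():
    """A deterministic unseen scene: 30% bloated / 15% semi / rest non-bloated."""
    spec = scene_for_coverage(30.0, 15.0, seed=99)
    img, truth = generate_colony_image(spec)
    return spec, img, truth
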