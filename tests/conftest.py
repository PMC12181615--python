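import numpy as np
import pytest

from cmhq import segmentation_ml as mlseg
from cmhq.synthetic_slides import SlideSimConfig, generate_stack


@pytest.fixture(scope="session")
def default_cfg():
    """The default study conditions (40 sections, 30 bleeds, artifacts on)."""
    return SlideSimConfig(rng_seed=1)


@pytest.fixture(scope="session")
def default_stack(default_cfg):
    return generate_stack(default_cfg)


@pytest.fixture(scope="session")
def clean_cfg():
    """Noise-free, artifact-free, jitter-free conditions for exact oracles."""
    return SlideSimConfig(rng_seed=1, noise_sigma=0.0, artifact_rate=0.0,
                          stain_intensity_jitter=0.0)


@pytest.fixture(scope="session")
def clean_stack(clean_cfg):
    return generate_stack(clean_cfg)


def train_on_stack(images, truth, n_train_sections=3, seed=0):
    """Train the pixel classifier on the first bleed-bearing sections."""
    secs = [s.section_index for s in truth.sections if len(s.objects)]
    train_idx = secs[:n_train_sections]
    anns = [
        mlseg.annotations_from_masks(
            images[i], truth.sections[i].tissue_mask,
            truth.sections[i].bleed_labels > 0, rng=seed + i)
        for i in train_idx
    ]
    return mlseg.train_classifier(anns), train_idx


@pytest.fixture(scope="session")
def trained_model(default_stack):
    images, truth = default_stack
    model, train_idx = train_on_stack(images, truth)
    return model, train_idx
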