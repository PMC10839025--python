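"""Shared fixtures: a tiny synthetic dataset and its derived artifacts.

Everything is generated programmatically; heavy objects are session-scoped
so extraction cost is paid once.
"""

import numpy as np
import pytest

from gasfeeg import (
    ExtractorConfig,
    SyntheticConfig,
    extract_batch,
    generate_dataset,
    signal_to_images,
)

FAST_SIFT = ExtractorConfig(method="sift", sift_upsampling=1, max_keypoints=200)
FAST_ORB = ExtractorConfig(method="orb", orb_bits=128, orb_n_keypoints=300)


@pytest.fixture(scope="session")
def tiny_signals():
    """4 labelled signals (2 per class), 2.5 s at 512 Hz -> 5 epochs each."""
    cfg = SyntheticConfig(n_per_class=2, duration_s=2.5, fs=512.0, seed=123)
    return generate_dataset(cfg)


@pytest.fixture(scope="session")
def tiny_images(tiny_signals):
    """GASF images of the tiny dataset with per-image labels and source ids."""
    images, labels, groups = [], [], []
    for sig in tiny_signals:
        for img in signal_to_images(sig):
            images.append(img)
            labels.append(sig.label)
            groups.append(sig.id)
    return images, np.asarray(labels), np.asarray(groups)


@pytest.fixture(scope="session")
def sift_sets(tiny_images):
    images, _, _ = tiny_images
    return extract_batch(images, FAST_SIFT)


@pytest.fixture(scope="session")
def orb_sets(tiny_images):
    images, _, _ = tiny_images
    return extract_batch(images, FAST_ORB)


@pytest.fixture(scope="session")
def blob_image():
    """256x256 image with one bright Gaussian blob (sigma=6 px) at (x=100, y=80)."""
    yy, xx = np.mgrid[0:256, 0:256]
    blob = 200.0 * np.exp(-(((xx - 100) ** 2) + ((yy - 80) ** 2)) / (2 * 6.0**2))
    return np.clip(40 + blob, 0, 255).astype(np.uint8)
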