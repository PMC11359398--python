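import numpy as np
import pytest

from histotex import (
    featurize_patchset,
    foreground_mask,
    generate_scene,
    histogram,
    otsu_threshold,
    standardize,
    tile_patches,
)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def scene4():
    """Default 4-class 600x600 synthetic scene (fixed seed)."""
    return generate_scene(n_classes=4, size=600, seed=3)


@pytest.fixture(scope="session")
def scene4_patches50(scene4):
    t = otsu_threshold(histogram(scene4.image))
    mask = foreground_mask(scene4.image, t)
    return tile_patches(scene4.image, mask, 50)


@pytest.fixture(scope="session")
def scene4_features(scene4_patches50):
    """Standardized feature table of the default scene at patch size 50."""
    return standardize(featurize_patchset(scene4_patches50))
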