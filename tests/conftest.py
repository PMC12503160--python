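import numpy as np
import pytest

from groovemap.silhouette import SilhouetteAtlas, make_silhouette


def flat_atlas(shape=(4, 4)) -> SilhouetteAtlas:
    """Fully in-mask rectangular atlas (single 'body' region) for stats tests."""
    return SilhouetteAtlas(labels=np.ones(shape, dtype=np.int16), names=("body",))


@pytest.fixture(scope="session")
def small_atlas() -> SilhouetteAtlas:
    """Reduced-resolution silhouette shared across spatial tests."""
    return make_silhouette((132, 64))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
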