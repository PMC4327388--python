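import numpy as np
import pytest

from spotcoloc import AcquisitionConfig, ParticleMap
from spotcoloc.detect import DetectionParams


@pytest.fixture
def cfg60():
    """x60/CoolSnap HQ-style acquisition: 107.5 nm/px, 2 px (215 nm) threshold."""
    return AcquisitionConfig(pixel_size_nm=107.5, threshold_px=2.0, channels=("a", "b"))


@pytest.fixture
def default_params():
    return DetectionParams()


@pytest.fixture
def random_map_factory():
    """Uniform (CSR) particle maps for matching/scrambling tests."""

    def make(n, seed, channel="a", field_shape=(256, 256), pixel_size_nm=107.5):
        rng = np.random.default_rng(seed)
        h, w = field_shape
        xy = rng.uniform([-0.5, -0.5], [w - 0.5, h - 0.5], size=(n, 2))
        return ParticleMap(
            xy=xy,
            brightness=rng.uniform(50, 500, size=n),
            channel=channel,
            field_shape=field_shape,
            pixel_size_nm=pixel_size_nm,
        )

    return make
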