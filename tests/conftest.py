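import numpy as np
import pytest

from vesselprox import BinaryVolume, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_volume(data, voxel=1.0, name="test"):
    return VolumeImage(np.asarray(data), voxel, name=name)


def make_mask(data, voxel=1.0, kind="vessel"):
    return BinaryVolume(np.asarray(data, dtype=bool), voxel, kind=kind)


def random_mask(rng, shape, density, ensure_mixed=True):
    """Random boolean grid; guaranteed to contain both classes."""
    m = rng.random(shape) < density
    if ensure_mixed:
        if not m.any():
            m[tuple(s // 2 for s in shape)] = True
        if m.all():
            m[0, 0, 0] = False
    return m
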