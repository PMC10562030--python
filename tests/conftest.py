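import numpy as np
import pytest

from psdcorr.phantom import PhantomConfig, make_head_phantom, make_distorted_pair
from psdcorr.volume import Mask3D, Volume3D
from psdcorr.warp import SequenceParams


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def default_phantom():
    """One 64-cubed head phantom shared across tests (read-only)."""
    return make_head_phantom(PhantomConfig(), seed=7)


@pytest.fixture(scope="session")
def default_case(default_phantom):
    """Distorted acquisition of the shared phantom at 220 Hz/px."""
    seq = SequenceParams(bandwidth_hz_per_px=220.0, freq_axis=0)
    return make_distorted_pair(default_phantom, seq)


def make_sphere_mask(shape=(32, 32, 32), center=None, radius=6.0, spacing=1.0):
    center = center or tuple((s - 1) / 2 for s in shape)
    g = np.indices(shape, dtype=float)
    r = np.sqrt(sum((gi - c) ** 2 for gi, c in zip(g, center)))
    aff = np.diag([spacing, spacing, spacing, 1.0])
    return Mask3D(r <= radius, aff)


def smooth_volume(shape=(64, 64, 64), freq_axis=0, seed=0):
    """Band-limited positive test image: sum of a few broad Gaussians."""
    rng = np.random.default_rng(seed)
    g = np.indices(shape, dtype=float)
    data = np.zeros(shape)
    for _ in range(4):
        c = rng.uniform(0.3, 0.7, 3) * np.array(shape)
        w = rng.uniform(5, 10)
        data += rng.uniform(0.5, 1.0) * np.exp(
            -sum((gi - ci) ** 2 for gi, ci in zip(g, c)) / (2 * w**2))
    return Volume3D(data, np.eye(4), freq_axis=freq_axis)
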