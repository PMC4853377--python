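import warnings

import numpy as np
import pytest

import serialrecon as sr

# Registration engines and morphology emit benign deprecation/convergence
# warnings at phantom scale; tests assert on results, not warnings.
warnings.simplefilter("ignore")


@pytest.fixture(scope="session")
def scene96():
    """Default-size phantom shared by the expensive end-to-end tests."""
    return sr.make_scene(seed=1)


@pytest.fixture(scope="session")
def scene64():
    """Small phantom for unit-level checks."""
    return sr.make_scene((64, 64, 48), seed=1)


@pytest.fixture(scope="session")
def blockface96(scene96):
    return sr.render_blockface(scene96, seed=2)


@pytest.fixture(scope="session")
def truth_as_blockface96(scene96):
    """The truth volume standing in for a perfectly reconstructed blockface."""
    return sr.ImageVolume(scene96.truth_volume.voxels, scene96.spacing)


def random_blob_mask(rng, shape, n_seeds=4, spacing=(1.0, 1.0, 1.0)):
    """Small random connected-ish mask for metric oracle tests."""
    bits = np.zeros(shape, dtype=bool)
    for _ in range(n_seeds):
        c = rng.integers(2, np.array(shape) - 2)
        r = rng.integers(1, 3)
        zz, yy, xx = np.ogrid[: shape[0], : shape[1], : shape[2]]
        bits |= (zz - c[0]) ** 2 + (yy - c[1]) ** 2 + (xx - c[2]) ** 2 <= r**2
    return sr.BinaryMask(bits, spacing)
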