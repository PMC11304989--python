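import numpy as np
import pytest

from nodulefpr.network import NetworkConfig
from nodulefpr.preprocess import ROI
from nodulefpr.volumes import NEGATIVE, POSITIVE, Volume


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def tiny_net_cfg():
    """A narrow network on small patches: fast enough for gradient checks."""
    return NetworkConfig(conv_kernels=(2, 3, 4), fc_nodes=(6, 6),
                         conv_dropout=0.0, fc_dropout=0.0, input_shape=(8, 8, 8))


def make_blob_rois(n_per_class: int, seed: int, shape=(8, 8, 8)):
    """Trivially separable patches: a bright central blob vs pure noise.

    Emulates the nodule-vs-background contrast at postage-stamp scale so
    training tests can learn something within a few dozen steps.
    """
    rng = np.random.default_rng(seed)
    rois = []
    zz, yy, xx = np.meshgrid(*[np.arange(s) - (s - 1) / 2 for s in shape],
                             indexing="ij")
    ball = (zz**2 + yy**2 + xx**2 <= (min(shape) / 3) ** 2).astype(np.float32)
    for label in (POSITIVE, NEGATIVE):
        for _ in range(n_per_class):
            patch = rng.normal(-0.8, 0.05, size=shape).astype(np.float32)
            if label == POSITIVE:
                patch = patch * (1 - ball) + ball * rng.normal(0.3, 0.05)
            rois.append(ROI(patch=np.clip(patch, -1, 1), label=label))
    return rois


@pytest.fixture
def blob_rois():
    return make_blob_rois(20, seed=7)


@pytest.fixture
def hu_volume():
    """A small HU-valued volume with a bright blob for ROI tests."""
    data = np.full((16, 64, 64), -850.0, dtype=np.float32)
    data[6:10, 28:36, 28:36] = 60.0
    return Volume(data=data, spacing=(2.0, 0.625, 0.625), origin=(0.0, 0.0, 0.0))
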