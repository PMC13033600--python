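import numpy as np
import pytest

from tilscope import SceneSpec, generate_scene
from tilscope.nn import Tensor


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_scene():
    """One deterministic 128x128 thumbnail-scale scene with ground truth."""
    return generate_scene(SceneSpec(width=128, height=128, seed=7))


@pytest.fixture(scope="session")
def detection_scene():
    """One high-magnification scene sized for lymphocyte detection."""
    return generate_scene(SceneSpec(width=128, height=128, seed=11, mpp=0.5,
                                    lymphocyte_density=2000,
                                    tumor_fraction=0.3))


class ConstantSegmenter:
    """Stub segmentation model emitting a constant probability."""

    def __init__(self, prob=0.8):
        self.prob = prob

    def set_training(self, flag):
        pass

    def __call__(self, x):
        n, _, h, w = x.shape
        return Tensor(np.full((n, 1, h, w), self.prob)), []


class SilentDetector:
    """Stub detector whose objectness is pinned far below threshold."""

    strides = (8, 16, 32)

    def set_training(self, flag):
        pass

    def __call__(self, x):
        n, _, h, w = x.shape
        out = []
        for s in self.strides:
            hg, wg = (h + s - 1) // s, (w + s - 1) // s
            out.append((Tensor(np.zeros((n, 12, hg, wg))),
                        Tensor(np.full((n, 3, hg, wg), -12.0)),
                        Tensor(np.zeros((n, 3, hg, wg)))))
        return out


class TopHalfSegmenter:
    """Stub segmentation model marking the top half of the frame."""

    def set_training(self, flag):
        pass

    def __call__(self, x):
        n, _, h, w = x.shape
        g = np.zeros((n, 1, h, w))
        g[:, :, :h // 2, :] = 0.9
        return Tensor(g), []


@pytest.fixture()
def stub_segmenter():
    return ConstantSegmenter()


@pytest.fixture()
def half_segmenter():
    return TopHalfSegmenter()


@pytest.fixture()
def stub_detector():
    return SilentDetector()
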