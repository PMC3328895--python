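import numpy as np
import pytest

from tearfilm.image import ChannelImage, RGBImage


@pytest.fixture()
def rng():
    return np.random.default_rng(20120405)


@pytest.fixture()
def random_rgb(rng):
    return RGBImage(rng.uniform(size=(48, 56, 3)))


@pytest.fixture()
def random_channel(rng):
    return ChannelImage(rng.uniform(size=(48, 56)))


@pytest.fixture()
def constant_rgb():
    return RGBImage(np.full((32, 32, 3), 0.5))


def pearson_ncc_oracle(image: np.ndarray, template: np.ndarray) -> np.ndarray:
    """Double-loop Pearson correlation of every valid template placement."""
    H, W = image.shape
    h, w = template.shape
    t = template - template.mean()
    t_norm = np.sqrt((t ** 2).sum())
    out = np.zeros((H - h + 1, W - w + 1))
    for r in range(H - h + 1):
        for c in range(W - w + 1):
            win = image[r:r + h, c:c + w]
            win0 = win - win.mean()
            denom = np.sqrt((win0 ** 2).sum()) * t_norm
            out[r, c] = 0.0 if denom < 1e-12 else (win0 * t).sum() / denom
    return out
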