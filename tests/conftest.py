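import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_gray_images(n, shape=(64, 64), seed=0):
    """Mixed-histogram random test images (gaussian / bimodal / skewed)."""
    out = []
    for s in range(n):
        r = np.random.default_rng(seed + s)
        kind = s % 3
        if kind == 0:
            img = r.normal(100, 25, shape)
        elif kind == 1:
            half = (shape[0] * shape[1]) // 2
            img = np.concatenate([
                r.normal(60, 15, half),
                r.normal(180, 20, shape[0] * shape[1] - half),
            ]).reshape(shape)
        else:
            img = (r.random(shape) ** 2) * 255
        out.append(np.clip(np.rint(img), 0, 255).astype(np.uint8))
    return out
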