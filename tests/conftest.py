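import numpy as np
import pytest

from stackbox import Box, Detection, GroundTruth


def make_det(x0, y0, x1, y1, score=0.9, model="m", image=0, cls=1):
    return Detection(Box(x0, y0, x1, y1), score, model, image, cls)


def make_gt(x0, y0, x1, y1, image=0, cls=1):
    return GroundTruth(Box(x0, y0, x1, y1), image, cls)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_boxes(rng, n, lo=0.0, hi=100.0, min_side=2.0, max_side=40.0):
    """n random valid float-coordinate boxes inside [lo, hi]²."""
    out = []
    for _ in range(n):
        w = rng.uniform(min_side, max_side)
        h = rng.uniform(min_side, max_side)
        x0 = rng.uniform(lo, hi - w)
        y0 = rng.uniform(lo, hi - h)
        out.append((x0, y0, x0 + w, y0 + h))
    return out
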