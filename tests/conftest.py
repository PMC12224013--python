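import numpy as np
import pytest

from pestkit.boxes import Box
from pestkit.dataset import AnnotatedImage, LabeledBox


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_annotated(
    h=60, w=80, color=(200, 30, 30), boxes=((20, 15, 60, 45),), source_id="img"
):
    """Solid-color annotated image with class-0 boxes (helper, not a fixture)."""
    pixels = np.zeros((h, w, 3), np.uint8)
    pixels[:] = color
    labels = [LabeledBox(Box(*b), 0) for b in boxes]
    return AnnotatedImage(pixels=pixels, labels=labels, source_id=source_id)


@pytest.fixture
def small_image():
    return make_annotated()


def random_box(rng, lo=0.0, hi=400.0, min_side=1.0, max_side=120.0) -> Box:
    x1, y1 = rng.uniform(lo, hi, 2)
    w, h = rng.uniform(min_side, max_side, 2)
    return Box(x1, y1, x1 + w, y1 + h)
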