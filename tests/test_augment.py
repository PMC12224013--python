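"""Mosaic/Mosaic-9/Mixup and static transforms with label remapping."""

import math

import numpy as np
import pytest

from pestkit.augment import (
    STATIC_KINDS,
    MixupConfig,
    MosaicConfig,
    clip_and_filter_labels,
    mixup,
    mosaic,
    mosaic9,
    static_transform,
)
from pestkit.boxes import Box
from pestkit.dataset import AnnotatedImage, LabeledBox

from conftest import make_annotated


def assert_labels_in_bounds(img: AnnotatedImage, min_area=4.0):
    for lb in img.labels:
        b = lb.box
        assert 0 <= b.x1 <= b.x2 <= img.width
        assert 0 <= b.y1 <= b.y2 <= img.height
        assert b.area >= min_area


# ------------------------------------------------------------ clip & filter

def test_clip_and_filter_labels():
    viewport = Box(0, 0, 100, 100)
    inside = LabeledBox(Box(10, 10, 40, 40), 2)
    outside = LabeledBox(Box(150, 150, 180, 180), 3)
    sliver = LabeledBox(Box(-30, 10, 1, 40), 4)  # clips to 1px wide
    kept = clip_and_filter_labels([inside, outside, sliver], viewport)
    assert kept == [inside]


def test_clip_threshold_drops_small_remnant():
    viewport = Box(0, 0, 100, 100)
    half_out = LabeledBox(Box(-8, 0, 2, 10), 0)  # 2x10 = 20 px after clip
    assert clip_and_filter_labels([half_out], viewport, min_area_px=25.0) == []
    kept = clip_and_filter_labels([half_out], viewport, min_area_px=10.0)
    assert kept[0].box == Box(0, 0, 2, 10)


# ----------------------------------------------------------------- mosaics

def four_sources():
    colors = [(255, 0, 0), (0, 255, 0), (0, 0, 255), (255, 255, 0)]
    return [
        make_annotated(h=50, w=70, color=c, boxes=((20, 15, 50, 35),), source_id=f"s{i}")
        for i, c in enumerate(colors)
    ]


def test_mosaic_conserves_central_boxes_and_pixels():
    cfg = MosaicConfig(out_size=(100, 100), n_tiles=4, jitter=0.0, seed=0)
    out = mosaic(four_sources(), cfg)
    assert out.pixels.shape == (100, 100, 3)
    assert len(out.labels) == 4
    assert_labels_in_bounds(out)
    # each quadrant carries its source's solid color
    quadrant_centers = [(25, 25), (25, 75), (75, 25), (75, 75)]  # (y, x) order
    expected = [(255, 0, 0), (0, 255, 0), (0, 0, 255), (255, 255, 0)]
    for (y, x), color in zip(quadrant_centers, expected):
        assert tuple(out.pixels[y, x]) == color


def test_mosaic_requires_four_images():
    with pytest.raises(ValueError):
        mosaic(four_sources()[:3], MosaicConfig(n_tiles=4))
    with pytest.raises(ValueError):
        mosaic(four_sources(), MosaicConfig(n_tiles=9))


def test_mosaic_seed_determinism():
    cfg = MosaicConfig(out_size=(96, 96), n_tiles=4, jitter=0.3, seed=11)
    a = mosaic(four_sources(), cfg)
    b = mosaic(four_sources(), cfg)
    assert np.array_equal(a.pixels, b.pixels)
    assert a.labels == b.labels


def nine_sources():
    return [
        make_annotated(
            h=60, w=80, color=((i + 1) * 25, 0, 0),
            boxes=((20, 15, 60, 45),), source_id=f"s{i}",
        )
        for i in range(9)
    ]


def test_mosaic9_tile_provenance_and_label_count():
    cfg = MosaicConfig(out_size=(90, 90), n_tiles=9, jitter=0.0, seed=0)
    out = mosaic9(nine_sources(), cfg)
    assert out.pixels.shape == (90, 90, 3)
    assert len(out.labels) == 9
    assert_labels_in_bounds(out)
    for row in range(3):
        for col in range(3):
            tile_color = (row * 3 + col + 1) * 25
            assert out.pixels[row * 30 + 15, col * 30 + 15, 0] == tile_color


def test_mosaic9_zero_jitter_partitions_exactly():
    """With no jitter, the 9 tiles cover the canvas with no gaps."""
    black = [
        make_annotated(h=40, w=40, color=(0, 0, 0), boxes=(), source_id=f"b{i}")
        for i in range(9)
    ]
    out = mosaic9(black, MosaicConfig(out_size=(100, 100), n_tiles=9, jitter=0.0))
    assert np.array_equal(out.pixels, np.zeros((100, 100, 3), np.uint8))
    # nonzero fill marks every pixel exactly once
    marks = np.zeros((100, 100), int)
    bounds = [0, 33, 67, 100]
    for r in range(3):
        for c in range(3):
            marks[bounds[r]:bounds[r + 1], bounds[c]:bounds[c + 1]] += 1
    assert (marks == 1).all()


def test_mosaic9_requires_nine_images():
    with pytest.raises(ValueError):
        mosaic9(nine_sources()[:8])


def test_mosaic9_jitter_stays_deterministic_and_in_bounds():
    cfg = MosaicConfig(out_size=(120, 120), n_tiles=9, jitter=0.4, seed=21)
    a = mosaic9(nine_sources(), cfg)
    b = mosaic9(nine_sources(), cfg)
    assert np.array_equal(a.pixels, b.pixels) and a.labels == b.labels
    assert_labels_in_bounds(a)


# ------------------------------------------------------------------- mixup

def test_mixup_endpoint_lambda_one():
    a = make_annotated(color=(10, 20, 30), boxes=((5, 5, 20, 20),), source_id="a")
    b = make_annotated(color=(200, 100, 50), boxes=((30, 25, 60, 40),), source_id="b")
    out = mixup(a, b, MixupConfig(fixed_lambda=1.0))
    assert np.array_equal(out.pixels, a.pixels)
    assert len(out.labels) == len(a.labels) + len(b.labels)
    assert {lb.class_id for lb in out.labels} == {0}


def test_mixup_half_rounds_half_up():
    a = make_annotated(color=(0, 0, 0), boxes=())
    b = make_annotated(color=(255, 255, 255), boxes=())
    out = mixup(a, b, MixupConfig(fixed_lambda=0.5))
    assert (out.pixels == 128).all()  # 127.5 rounds half-up


def test_mixup_convex_combination_exact(rng):
    lam = 0.3
    ap = rng.integers(0, 256, (20, 30, 3), dtype=np.uint8)
    bp = rng.integers(0, 256, (20, 30, 3), dtype=np.uint8)
    a = AnnotatedImage(ap, [], "a")
    b = AnnotatedImage(bp, [], "b")
    out = mixup(a, b, MixupConfig(fixed_lambda=lam))
    expected = np.floor(lam * ap.astype(float) + (1 - lam) * bp.astype(float) + 0.5)
    assert np.array_equal(out.pixels, expected.astype(np.uint8))


def test_mixup_shape_mismatch_rejected():
    a = make_annotated(h=50, w=70)
    b = make_annotated(h=60, w=70)
    with pytest.raises(ValueError):
        mixup(a, b)


def test_mixup_beta_lambda_deterministic_under_seed():
    a = make_annotated(color=(10, 10, 10), boxes=())
    b = make_annotated(color=(200, 200, 200), boxes=())
    cfg = MixupConfig(alpha=8.0, seed=4)
    assert np.array_equal(mixup(a, b, cfg).pixels, mixup(a, b, cfg).pixels)


# --------------------------------------------------------- static transforms

def test_hflip_mirrors_boxes():
    img = make_annotated(h=100, w=100, boxes=((10, 20, 30, 40),))
    out = static_transform(img, "hflip")
    assert out.labels[0].box == Box(70, 20, 90, 40)
    assert np.array_equal(out.pixels, img.pixels[:, ::-1])


def test_vflip_mirrors_boxes():
    img = make_annotated(h=100, w=100, boxes=((10, 20, 30, 40),))
    out = static_transform(img, "vflip")
    assert out.labels[0].box == Box(10, 60, 30, 80)


def test_scale_doubles_boxes():
    img = make_annotated(h=50, w=50, boxes=((5, 5, 10, 10),))
    out = static_transform(img, "scale", {"fx": 2.0})
    assert out.pixels.shape == (100, 100, 3)
    assert out.labels[0].box == Box(10, 10, 20, 20)


def test_rotation_90_matches_corner_oracle():
    """A 90-degree turn of a square image maps boxes analytically."""
    img = make_annotated(h=100, w=100, boxes=((70, 10, 90, 20),))
    out = static_transform(img, "rotate", {"angle": 90})
    # counterclockwise: (x, y) -> (y, W - x)
    b = out.labels[0].box
    assert (b.x1, b.y1, b.x2, b.y2) == pytest.approx((10, 10, 20, 30), abs=1e-9)
    assert out.pixels.shape == (100, 100, 3)


def test_rotation_arbitrary_angle_box_bounds_content():
    img = make_annotated(h=80, w=120, color=(0, 0, 0), boxes=())
    img.pixels[30:50, 60:100] = 255
    img.labels.append(LabeledBox(Box(60, 30, 100, 50), 1))
    out = static_transform(img, "rotate", {"angle": 33.0})
    b = out.labels[0].box
    ys, xs = np.nonzero(out.pixels[:, :, 0] > 200)
    assert b.x1 - 1.5 <= xs.min() and xs.max() + 1 <= b.x2 + 1.5
    assert b.y1 - 1.5 <= ys.min() and ys.max() + 1 <= b.y2 + 1.5


def test_center_crop_shifts_and_clips():
    img = make_annotated(h=100, w=100, boxes=((40, 40, 60, 60),))
    out = static_transform(img, "center_crop", {"size": (50, 50)})
    assert out.pixels.shape == (50, 50, 3)
    assert out.labels[0].box == Box(15, 15, 35, 35)


def test_random_crop_scale_restores_size():
    img = make_annotated(h=64, w=64, boxes=((10, 10, 50, 50),))
    out = static_transform(img, "random_crop_scale", {"size": (32, 32)}, seed=5)
    assert out.pixels.shape == (64, 64, 3)
    assert_labels_in_bounds(out)


def test_edge_pad_offsets_boxes():
    img = make_annotated(h=40, w=40, boxes=((5, 5, 15, 15),))
    out = static_transform(img, "edge_pad", {"pad": 10})
    assert out.pixels.shape == (60, 60, 3)
    assert out.labels[0].box == Box(15, 15, 25, 25)


@pytest.mark.parametrize("kind", ["grayscale", "color_dither"])
def test_photometric_transforms_preserve_labels(kind):
    img = make_annotated(boxes=((20, 15, 60, 45),))
    out = static_transform(img, kind, seed=3)
    assert [lb.box for lb in out.labels] == [lb.box for lb in img.labels]
    assert out.pixels.shape == img.pixels.shape


def test_affine_identity_preserves_boxes():
    img = make_annotated(h=50, w=70, boxes=((10, 10, 30, 30),))
    out = static_transform(img, "affine", {"matrix": [[1, 0, 0], [0, 1, 0]]})
    assert out.labels[0].box == Box(10, 10, 30, 30)


def test_affine_shear_remaps_corners():
    img = make_annotated(h=100, w=100, boxes=((10, 10, 30, 30),))
    out = static_transform(img, "affine", {"matrix": [[1, 0.5, 0], [0, 1, 0]]})
    # corners (x + 0.5y, y): hull x from 10+5=15 to 30+15=45
    assert out.labels[0].box == Box(15, 10, 45, 30)


def test_unknown_kind_rejected(small_image):
    with pytest.raises(ValueError):
        static_transform(small_image, "solarize")


@pytest.mark.parametrize("kind", sorted(STATIC_KINDS))
def test_every_kind_is_deterministic_and_in_bounds(kind):
    img = make_annotated(h=64, w=96, boxes=((20, 15, 60, 45), (5, 5, 15, 18)))
    params = {"size": (32, 48)} if "crop" in kind else {}
    a = static_transform(img, kind, params, seed=9)
    b = static_transform(img, kind, params, seed=9)
    assert np.array_equal(a.pixels, b.pixels)
    assert a.labels == b.labels
    assert_labels_in_bounds(a)
    # class ids never change
    assert {lb.class_id for lb in a.labels} <= {lb.class_id for lb in img.labels}
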