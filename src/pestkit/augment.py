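"""Mosaic, Mosaic-9 and Mixup augmentation with exact label remapping.

Mosaic stitches four randomly chosen labeled images into a 2 x 2
composite around a jittered center; Mosaic-9 extends this to a 3 x 3
grid with jittered interior boundaries, raising scene complexity and
the share of small objects.  Mixup blends two images pixelwise with a
convex weight lambda and takes the union of their label lists.  A
registry of static (offline) transforms covers the classic
dataset-expansion operations: scaling, grayscale, crops, padding,
rotation, flips, color dithering and general affine warps.

Every geometric transform remaps boxes through the exact same mapping
applied to the pixels, then clips them to the output viewport and
drops slivers (area below ``min_box_area_px`` or a side shorter than 2
pixels).  Photometric transforms leave labels untouched.  All
randomness is drawn from an explicit seed, so each operation is a pure
function of (inputs, config).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from PIL import Image

from .boxes import Box, normalize_box
from .dataset import AnnotatedImage, LabeledBox

__all__ = [
    "MosaicConfig",
    "MixupConfig",
    "clip_and_filter_labels",
    "mosaic",
    "mosaic9",
    "mixup",
    "static_transform",
    "STATIC_KINDS",
]

MIN_BOX_SIDE_PX = 2.0  # clipped boxes thinner than this are dropped


@dataclass(frozen=True)
class MosaicConfig:
    """Layout parameters for mosaic stitching.

    out_size : output (height, width) in pixels.
    n_tiles : 4 (2x2) or 9 (3x3).
    jitter : cell-boundary jitter as a fraction of the output size,
        in [0, 0.4]; 0 gives an exact even grid.
    min_box_area_px : labels clipped below this area are dropped.
    """

    out_size: tuple[int, int] = (640, 640)
    n_tiles: int = 4
    jitter: float = 0.0
    min_box_area_px: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tiles not in (4, 9):
            raise ValueError(f"n_tiles must be 4 or 9, got {self.n_tiles}")
        if not (0.0 <= self.jitter <= 0.4):
            raise ValueError(f"jitter must be in [0, 0.4], got {self.jitter}")
        if min(self.out_size) < 1:
            raise ValueError(f"out_size must be positive, got {self.out_size}")


@dataclass(frozen=True)
class MixupConfig:
    """Mixing law for mixup: lambda ~ Beta(alpha, alpha), or fixed."""

    alpha: float = 8.0
    fixed_lambda: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if self.fixed_lambda is not None and not 0.0 <= self.fixed_lambda <= 1.0:
            raise ValueError(f"fixed_lambda must be in [0,1], got {self.fixed_lambda}")


def clip_and_filter_labels(
    labels: Sequence[LabeledBox],
    viewport: Box,
    min_area_px: float = 4.0,
    min_side_px: float = MIN_BOX_SIDE_PX,
) -> list[LabeledBox]:
    """Intersect each box with the viewport; drop slivers.

    Surviving boxes lie entirely within the viewport and have area
    >= min_area_px and both sides >= min_side_px.
    """
    out = []
    for lb in labels:
        b = lb.box
        clipped = Box(
            max(b.x1, viewport.x1),
            max(b.y1, viewport.y1),
            min(b.x2, viewport.x2),
            min(b.y2, viewport.y2),
        )
        w, h = clipped.x2 - clipped.x1, clipped.y2 - clipped.y1
        if w >= min_side_px and h >= min_side_px and w * h >= min_area_px:
            out.append(LabeledBox(box=clipped, class_id=lb.class_id))
    return out


def _resize(pixels: np.ndarray, size_wh: tuple[int, int]) -> np.ndarray:
    return np.asarray(Image.fromarray(pixels).resize(size_wh, Image.BILINEAR))


def _paste_cell(
    canvas: np.ndarray,
    src: AnnotatedImage,
    x0: int,
    y0: int,
    x1: int,
    y1: int,
    cfg: MosaicConfig,
) -> list[LabeledBox]:
    """Resize one source into a cell; return its remapped, clipped labels."""
    cw, ch = x1 - x0, y1 - y0
    canvas[y0:y1, x0:x1] = _resize(src.pixels, (cw, ch))
    sx, sy = cw / src.width, ch / src.height
    remapped = [
        LabeledBox(
            box=Box(
                lb.box.x1 * sx + x0,
                lb.box.y1 * sy + y0,
                lb.box.x2 * sx + x0,
                lb.box.y2 * sy + y0,
            ),
            class_id=lb.class_id,
        )
        for lb in src.labels
    ]
    return clip_and_filter_labels(
        remapped, Box(x0, y0, x1, y1), cfg.min_box_area_px
    )


def _jittered_boundaries(
    extent: int, n_cells: int, jitter: float, rng: np.random.Generator
) -> list[int]:
    """Interior cell boundaries of an even grid, each jittered by
    +-jitter*extent, clamped so every cell keeps >= 1 px."""
    bounds = [0]
    for i in range(1, n_cells):
        b = extent * i / n_cells + rng.uniform(-jitter, jitter) * extent
        bounds.append(int(round(min(max(b, bounds[-1] + 1), extent - (n_cells - i)))))
    bounds.append(extent)
    return bounds


def mosaic(images: Sequence[AnnotatedImage], cfg: MosaicConfig = MosaicConfig()) -> AnnotatedImage:
    """Stitch four labeled images into a 2 x 2 composite."""
    if cfg.n_tiles != 4:
        raise ValueError(f"mosaic requires n_tiles=4, got {cfg.n_tiles}")
    if len(images) < 4:
        raise ValueError(f"mosaic needs 4 images, got {len(images)}")
    return _mosaic_grid(images[:4], 2, cfg)


def mosaic9(images: Sequence[AnnotatedImage], cfg: MosaicConfig | None = None) -> AnnotatedImage:
    """Stitch nine labeled images into a 3 x 3 composite."""
    if cfg is None:
        cfg = MosaicConfig(n_tiles=9)
    if cfg.n_tiles != 9:
        raise ValueError(f"mosaic9 requires n_tiles=9, got {cfg.n_tiles}")
    if len(images) < 9:
        raise ValueError(f"mosaic9 needs 9 images, got {len(images)}")
    return _mosaic_grid(images[:9], 3, cfg)


def _mosaic_grid(
    images: Sequence[AnnotatedImage], n: int, cfg: MosaicConfig
) -> AnnotatedImage:
    h, w = cfg.out_size
    rng = np.random.default_rng(cfg.seed)
    xb = _jittered_boundaries(w, n, cfg.jitter, rng)
    yb = _jittered_boundaries(h, n, cfg.jitter, rng)
    canvas = np.zeros((h, w, 3), dtype=np.uint8)
    labels: list[LabeledBox] = []
    for row in range(n):
        for col in range(n):
            src = images[row * n + col]
            labels += _paste_cell(
                canvas, src, xb[col], yb[row], xb[col + 1], yb[row + 1], cfg
            )
    return AnnotatedImage(
        pixels=canvas,
        labels=labels,
        source_id="mosaic(" + ",".join(im.source_id for im in images) + ")",
    )


def mixup(
    a: AnnotatedImage, b: AnnotatedImage, cfg: MixupConfig = MixupConfig()
) -> AnnotatedImage:
    """Convex pixel blend ``lam*a + (1-lam)*b`` with the union of labels.

    Inputs must already share a shape (resizing is the caller's static
    transform).  Blending happens in floating point and is quantized by
    round-half-up to 8 bits.  Labels are concatenated with classes
    preserved, the standard detection-mixup convention.
    """
    if a.pixels.shape != b.pixels.shape:
        raise ValueError(
            f"mixup inputs must share a shape: {a.pixels.shape} vs {b.pixels.shape}"
        )
    if cfg.fixed_lambda is not None:
        lam = cfg.fixed_lambda
    else:
        lam = float(np.random.default_rng(cfg.seed).beta(cfg.alpha, cfg.alpha))
    blend = lam * a.pixels.astype(np.float64) + (1.0 - lam) * b.pixels.astype(np.float64)
    pixels = np.clip(np.floor(blend + 0.5), 0, 255).astype(np.uint8)
    return AnnotatedImage(
        pixels=pixels,
        labels=list(a.labels) + list(b.labels),
        source_id=f"mixup({a.source_id},{b.source_id},lam={lam:.4f})",
    )


# ---------------------------------------------------------------------------
# Static (offline) transforms
# ---------------------------------------------------------------------------

def _remap_boxes_affine(
    labels: Sequence[LabeledBox],
    fwd: Callable[[float, float], tuple[float, float]],
) -> list[LabeledBox]:
    """Map each box to the axis-aligned hull of its transformed corners."""
    out = []
    for lb in labels:
        b = lb.box
        pts = [fwd(x, y) for x in (b.x1, b.x2) for y in (b.y1, b.y2)]
        xs, ys = zip(*pts)
        out.append(
            LabeledBox(
                box=normalize_box(min(xs), min(ys), max(xs), max(ys)),
                class_id=lb.class_id,
            )
        )
    return out


def _finish(pixels, labels, src, kind, geometric=True, min_area=4.0):
    h, w = pixels.shape[:2]
    if geometric:
        labels = clip_and_filter_labels(labels, Box(0, 0, w, h), min_area)
    return AnnotatedImage(
        pixels=np.ascontiguousarray(pixels),
        labels=list(labels),
        source_id=f"{kind}({src.source_id})",
    )


def _t_scale(img, params, rng):
    fx = params.get("fx", 2.0)
    fy = params.get("fy", fx)
    new_w, new_h = max(1, round(img.width * fx)), max(1, round(img.height * fy))
    sx, sy = new_w / img.width, new_h / img.height
    pixels = _resize(img.pixels, (new_w, new_h))
    labels = _remap_boxes_affine(img.labels, lambda x, y: (x * sx, y * sy))
    return _finish(pixels, labels, img, "scale")


def _t_grayscale(img, params, rng):
    lum = img.pixels @ np.array([0.299, 0.587, 0.114])
    pixels = np.clip(np.floor(lum + 0.5), 0, 255).astype(np.uint8)
    return _finish(
        np.repeat(pixels[:, :, None], 3, axis=2), img.labels, img, "grayscale",
        geometric=False,
    )


def _crop(img, x0, y0, cw, ch, kind):
    pixels = img.pixels[y0 : y0 + ch, x0 : x0 + cw]
    labels = _remap_boxes_affine(img.labels, lambda x, y: (x - x0, y - y0))
    return _finish(pixels, labels, img, kind)


def _crop_size(img, params):
    ch, cw = params.get("size", (img.height // 2, img.width // 2))
    if not (1 <= cw <= img.width and 1 <= ch <= img.height):
        raise ValueError(f"crop size {(ch, cw)} exceeds image {img.height}x{img.width}")
    return ch, cw


def _t_center_crop(img, params, rng):
    ch, cw = _crop_size(img, params)
    return _crop(img, (img.width - cw) // 2, (img.height - ch) // 2, cw, ch, "center_crop")


def _t_random_crop(img, params, rng):
    ch, cw = _crop_size(img, params)
    x0 = int(rng.integers(0, img.width - cw + 1))
    y0 = int(rng.integers(0, img.height - ch + 1))
    return _crop(img, x0, y0, cw, ch, "random_crop")


def _t_random_crop_scale(img, params, rng):
    cropped = _t_random_crop(img, params, rng)
    sx, sy = img.width / cropped.width, img.height / cropped.height
    pixels = _resize(cropped.pixels, (img.width, img.height))
    labels = _remap_boxes_affine(cropped.labels, lambda x, y: (x * sx, y * sy))
    return _finish(pixels, labels, img, "random_crop_scale")


def _t_edge_pad(img, params, rng):
    pad = params.get("pad", 16)
    if isinstance(pad, int):
        top = bottom = left = right = pad
    else:
        top, bottom, left, right = pad
    pixels = np.pad(
        img.pixels, ((top, bottom), (left, right), (0, 0)), mode="edge"
    )
    labels = _remap_boxes_affine(img.labels, lambda x, y: (x + left, y + top))
    return _finish(pixels, labels, img, "edge_pad")


def _t_rotate(img, params, rng):
    angle = params.get("angle")
    if angle is None:
        angle = float(rng.uniform(-30.0, 30.0))
    pil = Image.fromarray(img.pixels).rotate(
        angle, resample=Image.BILINEAR, expand=True
    )
    pixels = np.asarray(pil)
    new_h, new_w = pixels.shape[:2]
    theta = math.radians(angle)
    cx, cy = img.width / 2.0, img.height / 2.0
    ncx, ncy = new_w / 2.0, new_h / 2.0
    cos_t, sin_t = math.cos(theta), math.sin(theta)

    # forward map matching PIL's counterclockwise rotation about the
    # image center (y axis points down in array coordinates)
    def fwd(x, y):
        dx, dy = x - cx, y - cy
        return (cos_t * dx + sin_t * dy + ncx, -sin_t * dx + cos_t * dy + ncy)

    labels = _remap_boxes_affine(img.labels, fwd)
    return _finish(pixels, labels, img, "rotate")


def _t_hflip(img, params, rng):
    w = img.width
    labels = _remap_boxes_affine(img.labels, lambda x, y: (w - x, y))
    return _finish(img.pixels[:, ::-1], labels, img, "hflip")


def _t_vflip(img, params, rng):
    h = img.height
    labels = _remap_boxes_affine(img.labels, lambda x, y: (x, h - y))
    return _finish(img.pixels[::-1], labels, img, "vflip")


def _t_color_dither(img, params, rng):
    gain_range = params.get("gain", 0.2)
    shift_range = params.get("shift", 20.0)
    gains = rng.uniform(1 - gain_range, 1 + gain_range, size=3)
    shifts = rng.uniform(-shift_range, shift_range, size=3)
    pixels = np.clip(
        np.floor(img.pixels * gains + shifts + 0.5), 0, 255
    ).astype(np.uint8)
    return _finish(pixels, img.labels, img, "color_dither", geometric=False)


def _t_affine(img, params, rng):
    m = params.get("matrix")
    if m is None:
        # small random shear + scale around identity
        m = [
            [1 + rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1), rng.uniform(-10, 10)],
            [rng.uniform(-0.1, 0.1), 1 + rng.uniform(-0.1, 0.1), rng.uniform(-10, 10)],
        ]
    (a, b, tx), (c, d, ty) = m
    det = a * d - b * c
    if abs(det) < 1e-12:
        raise ValueError("affine matrix is singular")
    # PIL's transform takes the inverse (output -> input) coefficients
    inv = (d / det, -b / det, (b * ty - d * tx) / det,
           -c / det, a / det, (c * tx - a * ty) / det)
    pil = Image.fromarray(img.pixels).transform(
        (img.width, img.height), Image.AFFINE, inv, resample=Image.BILINEAR
    )
    labels = _remap_boxes_affine(
        img.labels, lambda x, y: (a * x + b * y + tx, c * x + d * y + ty)
    )
    return _finish(np.asarray(pil), labels, img, "affine")


STATIC_KINDS: dict[str, Callable] = {
    "scale": _t_scale,
    "grayscale": _t_grayscale,
    "center_crop": _t_center_crop,
    "random_crop": _t_random_crop,
    "random_crop_scale": _t_random_crop_scale,
    "edge_pad": _t_edge_pad,
    "rotate": _t_rotate,
    "hflip": _t_hflip,
    "vflip": _t_vflip,
    "color_dither": _t_color_dither,
    "affine": _t_affine,
}


def static_transform(
    img: AnnotatedImage, kind: str, params: dict | None = None, seed: int = 0
) -> AnnotatedImage:
    """Apply one registered static transform.

    Geometric kinds remap labels through the exact pixel mapping and
    clip/filter the result; photometric kinds (grayscale,
    color_dither) leave labels unchanged.  Unknown kinds are rejected.
    """
    if kind not in STATIC_KINDS:
        raise ValueError(
            f"unknown transform kind {kind!r}; known: {sorted(STATIC_KINDS)}"
        )
    rng = np.random.default_rng(seed)
    return STATIC_KINDS[kind](img, params or {}, rng)
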