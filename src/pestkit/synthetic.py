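"""Deterministic synthetic fixtures for every pipeline input.

Real pest imagery is not redistributable, so tests and demos run on
generated data that reproduces the structural features the methods
care about:

* labeled scenes — colored elliptical "pests" on a textured
  background, with a size law weighted toward small objects (area
  below the 32x32-pixel small-object cutoff), mirroring the
  small-object-heavy profile of field pest datasets;
* planted evaluation sets — detections constructed so that greedy
  matching at IoU 0.5 reproduces a prescribed TP/FP flag sequence per
  class, with the implied average precision stored alongside (the
  fixture is self-verifying);
* categorized box pairs for loss properties (identical, nested,
  equal-size offset, disjoint, random);
* clustered (w, h) mixtures for anchor-recovery tests.

Every generator is a pure function of its spec and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image

from .boxes import Box
from .dataset import (
    AnnotatedImage,
    ClassRegistry,
    ImageAnnotation,
    LabeledBox,
    write_voc_xml,
    write_yolo_txt,
)

__all__ = [
    "SMALL_OBJECT_AREA_PX",
    "SceneSpec",
    "PlantedEval",
    "BoxPair",
    "gen_scene",
    "gen_planted_eval",
    "gen_box_pairs",
    "gen_anchor_mixture",
    "write_scene",
]

logger = logging.getLogger(__name__)

#: COCO-convention cutoff below which a box counts as a small object.
SMALL_OBJECT_AREA_PX = 32 * 32

# uniform side ranges (pixels) per size category; small sides stay
# below 32 so every small object is under the area cutoff
_SIZE_RANGES = {"small": (8, 31), "medium": (40, 96), "large": (100, 200)}


@dataclass(frozen=True)
class SceneSpec:
    """Recipe for one synthetic labeled scene.

    size_weights defaults to (0.8, 0.15, 0.05) over (small, medium,
    large) objects — a small-object-heavy mixture.  class_probs
    defaults to uniform over the 12-class registry.
    """

    image_size: tuple[int, int] = (640, 640)  # (H, W)
    n_objects: int = 8
    class_probs: tuple[float, ...] | None = None
    size_weights: tuple[float, float, float] = (0.8, 0.15, 0.05)
    n_classes: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.image_size) < 32:
            raise ValueError(f"image_size too small: {self.image_size}")
        if self.n_objects < 0:
            raise ValueError("n_objects must be >= 0")
        if abs(sum(self.size_weights) - 1.0) > 1e-9:
            raise ValueError("size_weights must sum to 1")
        if self.class_probs is not None:
            if len(self.class_probs) != self.n_classes:
                raise ValueError("class_probs length must equal n_classes")
            if abs(sum(self.class_probs) - 1.0) > 1e-9:
                raise ValueError("class_probs must sum to 1")


def _textured_background(h: int, w: int, rng: np.random.Generator) -> np.ndarray:
    low = rng.integers(40, 216, size=(8, 8, 3), dtype=np.uint8)
    return np.asarray(Image.fromarray(low).resize((w, h), Image.BILINEAR))


def _draw_ellipse(pixels: np.ndarray, box: Box, color: np.ndarray) -> None:
    h, w = pixels.shape[:2]
    yy, xx = np.mgrid[0:h, 0:w]
    cx, cy = (box.x1 + box.x2) / 2, (box.y1 + box.y2) / 2
    rx, ry = max(box.width / 2, 1.0), max(box.height / 2, 1.0)
    mask = ((xx - cx) / rx) ** 2 + ((yy - cy) / ry) ** 2 <= 1.0
    pixels[mask] = color


def gen_scene(spec: SceneSpec = SceneSpec()) -> AnnotatedImage:
    """Render one labeled scene: ellipses on a textured background.

    Objects are placed without overlap by rejection sampling; if a
    placement cannot be found after bounded retries the scene carries
    fewer objects than requested (logged).
    """
    h, w = spec.image_size
    rng = np.random.default_rng(spec.seed)
    pixels = _textured_background(h, w, rng).copy()
    class_probs = spec.class_probs or tuple([1.0 / spec.n_classes] * spec.n_classes)

    labels: list[LabeledBox] = []
    placed: list[Box] = []
    for _ in range(spec.n_objects):
        category = ("small", "medium", "large")[
            rng.choice(3, p=np.asarray(spec.size_weights))
        ]
        lo, hi = _SIZE_RANGES[category]
        # objects never exceed the image extent
        bw = min(int(rng.integers(lo, hi + 1)), w)
        bh = min(int(rng.integers(lo, hi + 1)), h)
        box = None
        for _attempt in range(60):
            x0 = int(rng.integers(0, max(w - bw, 0) + 1))
            y0 = int(rng.integers(0, max(h - bh, 0) + 1))
            cand = Box(x0, y0, x0 + bw, y0 + bh)
            pad = 2.0  # keep a margin so ellipses never touch
            if all(
                cand.x2 + pad <= p.x1 or p.x2 + pad <= cand.x1
                or cand.y2 + pad <= p.y1 or p.y2 + pad <= cand.y1
                for p in placed
            ):
                box = cand
                break
        if box is None:
            logger.warning(
                "scene seed=%d: packing failed, placed %d of %d objects",
                spec.seed, len(labels), spec.n_objects,
            )
            break
        class_id = int(rng.choice(spec.n_classes, p=np.asarray(class_probs)))
        color = rng.integers(0, 256, size=3).astype(np.uint8)
        _draw_ellipse(pixels, box, color)
        placed.append(box)
        labels.append(LabeledBox(box=box, class_id=class_id))

    return AnnotatedImage(
        pixels=pixels, labels=labels, source_id=f"scene_{spec.seed}"
    )


def write_scene(
    img: AnnotatedImage, out_dir, registry: ClassRegistry = ClassRegistry()
) -> None:
    """Save a scene as PNG + VOC XML + YOLO txt under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    Image.fromarray(img.pixels).save(out_dir / f"{img.source_id}.png")
    ann = ImageAnnotation(
        source_id=img.source_id,
        width=img.width,
        height=img.height,
        labels=tuple(img.labels),
    )
    write_voc_xml(ann, out_dir / f"{img.source_id}.xml", registry)
    write_yolo_txt(img.labels, out_dir / f"{img.source_id}.txt", (img.width, img.height))


# ---------------------------------------------------------------------------
# Planted evaluation fixtures
# ---------------------------------------------------------------------------

def _ap_from_flags(flags: Sequence[bool], n_gt: int) -> float:
    """All-point-interpolated AP computed directly from ranked flags.

    Brute force by definition: for each recall level reached, take the
    maximum precision at any rank whose recall is at least that level,
    and sum over recall increments.  O(n^2); used to stamp the
    fixture's expected values.
    """
    if n_gt < 1:
        return 0.0
    tp = 0
    recalls, precisions = [], []
    for i, f in enumerate(flags, start=1):
        tp += bool(f)
        recalls.append(tp / n_gt)
        precisions.append(tp / i)
    ap = 0.0
    prev_r = 0.0
    for i, f in enumerate(flags):
        if not f:
            continue
        r = recalls[i]
        p_interp = max(p for p, rr in zip(precisions, recalls) if rr >= r)
        ap += (r - prev_r) * p_interp
        prev_r = r
    return ap


@dataclass(frozen=True)
class PlantedEval:
    """Self-verifying evaluation fixture.

    Running greedy matching at IoU 0.5 on (detections, ground_truths)
    reproduces ``flags_per_class`` exactly, and the per-class AP of the
    induced P-R curve equals ``expected_ap``.
    """

    ground_truths: tuple
    detections: tuple
    flags_per_class: dict[int, tuple[bool, ...]]
    n_gt_per_class: dict[int, int]
    expected_ap: dict[int, float]
    expected_map: float = field(default=0.0)


def gen_planted_eval(
    flags_per_class: dict[int, Sequence[bool]],
    n_gt_per_class: dict[int, int],
    seed: int = 0,
) -> PlantedEval:
    """Construct geometry realizing prescribed per-class TP/FP sequences.

    Each class lives on its own image: ground truths sit on a sparse
    grid, a TP detection copies the next unmatched ground-truth box
    (IoU 1), an FP sits in empty space (IoU 0 with everything).
    Confidences decrease along each flag sequence, so ranked order
    equals flag order.  Rejects sequences with more TPs than ground
    truths.
    """
    from .evaluation import Detection, GroundTruth  # local: avoid cycle

    rng = np.random.default_rng(seed)
    gts: list = []
    dets: list = []
    flags_out: dict[int, tuple[bool, ...]] = {}
    expected: dict[int, float] = {}
    for class_id, flags in flags_per_class.items():
        flags = tuple(bool(f) for f in flags)
        n_gt = n_gt_per_class[class_id]
        if sum(flags) > n_gt:
            raise ValueError(
                f"class {class_id}: {sum(flags)} TPs exceed {n_gt} ground truths"
            )
        image_id = f"planted_{class_id}"
        gt_boxes = [Box(i * 100.0, 0.0, i * 100.0 + 50.0, 50.0) for i in range(n_gt)]
        gts += [GroundTruth(image_id, b, class_id) for b in gt_boxes]

        confs = np.linspace(0.95, 0.55, num=max(len(flags), 1))
        tp_used = 0
        for i, f in enumerate(flags):
            if f:
                box = gt_boxes[tp_used]
                tp_used += 1
            else:
                # far below the ground-truth row: IoU 0 with every GT
                box = Box(i * 100.0, 300.0 + rng.uniform(0, 20), i * 100.0 + 50.0, 360.0)
            dets.append(Detection(image_id, box, class_id, float(confs[i])))
        flags_out[class_id] = flags
        expected[class_id] = _ap_from_flags(flags, n_gt)

    return PlantedEval(
        ground_truths=tuple(gts),
        detections=tuple(dets),
        flags_per_class=flags_out,
        n_gt_per_class=dict(n_gt_per_class),
        expected_ap=expected,
        expected_map=float(np.mean(list(expected.values()))) if expected else 0.0,
    )


# ---------------------------------------------------------------------------
# Box pairs and anchor mixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoxPair:
    c: Box
    g: Box
    tag: str


_PAIR_LAWS = ("identical", "nested", "equal-size", "disjoint", "random", "mixed")


def gen_box_pairs(n: int, law: str = "mixed", seed: int = 0) -> list[BoxPair]:
    """Generate n categorized box pairs for loss property tests."""
    if n < 1:
        raise ValueError("n must be >= 1")
    if law not in _PAIR_LAWS:
        raise ValueError(f"unknown law {law!r}; known: {_PAIR_LAWS}")
    rng = np.random.default_rng(seed)
    laws = (
        ["identical", "nested", "equal-size", "disjoint", "random"]
        if law == "mixed"
        else [law]
    )
    pairs = []
    for i in range(n):
        tag = laws[i % len(laws)]
        x1, y1 = rng.uniform(0, 500, 2)
        w, h = rng.uniform(5, 120, 2)
        c = Box(x1, y1, x1 + w, y1 + h)
        if tag == "identical":
            g = c
        elif tag == "nested":
            fx, fy = rng.uniform(0.2, 0.8, 2)
            gw, gh = w * fx, h * fy
            gx = x1 + rng.uniform(0, w - gw)
            gy = y1 + rng.uniform(0, h - gh)
            g = Box(gx, gy, gx + gw, gy + gh)
        elif tag == "equal-size":
            dx, dy = rng.uniform(-150, 150, 2)
            g = c.shifted(dx, dy)
        elif tag == "disjoint":
            gw, gh = rng.uniform(5, 120, 2)
            gx = x1 + w + rng.uniform(5, 100)
            gy = y1 + h + rng.uniform(5, 100)
            g = Box(gx, gy, gx + gw, gy + gh)
        else:  # random
            gx, gy = rng.uniform(0, 500, 2)
            gw, gh = rng.uniform(5, 120, 2)
            g = Box(gx, gy, gx + gw, gy + gh)
        pairs.append(BoxPair(c=c, g=g, tag=tag))
    return pairs


def gen_anchor_mixture(
    centers: Sequence[tuple[float, float]],
    sigma: float = 1.0,
    n_per: int = 100,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Gaussian (w, h) samples around planted centers, floored at 1 px."""
    if len(centers) < 1:
        raise ValueError("need at least one planted center")
    rng = np.random.default_rng(seed)
    dims = []
    for cw, ch in centers:
        samples = rng.normal([cw, ch], sigma, size=(n_per, 2))
        samples = np.maximum(samples, 1.0)
        dims += [tuple(s) for s in samples]
    return dims
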