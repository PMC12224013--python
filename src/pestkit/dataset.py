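"""Dataset containers and I/O: PASCAL VOC XML, YOLO txt, train/val/test split.

The annotation dialect matches what the LabelImg tool writes: one XML
file per image with the image size and one ``object`` node per labeled
box (class name plus xmin/ymin/xmax/ymax corner pixels).  Corners are
used verbatim as continuous coordinates — no one-pixel offset
correction is applied.

The default class registry is the twelve pest classes of the passion
fruit pest dataset this toolkit targets.

The split procedure is two-stage: ids are shuffled, 2/10 are held out
for testing, and the remaining 8/10 are divided 7:3 into training and
validation — so the final fractions are 0.56 / 0.24 / 0.20.  Counts
use largest-remainder rounding so the three parts always partition the
input (6,000 ids give 3,360 / 1,440 / 1,200).
"""

from __future__ import annotations

import math
import xml.etree.ElementTree as ET
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .boxes import Box

__all__ = [
    "DEFAULT_CLASSES",
    "ClassRegistry",
    "LabeledBox",
    "AnnotatedImage",
    "ImageAnnotation",
    "DatasetSplit",
    "read_voc_xml",
    "write_voc_xml",
    "read_yolo_txt",
    "write_yolo_txt",
    "split_dataset",
    "discover_pairs",
]

#: The twelve pest classes, in registry order (abbreviated species names).
DEFAULT_CLASSES: tuple[str, ...] = (
    "Bd", "elater", "Er", "Hh", "PlA", "PlL",
    "Rs", "Sb", "Sc", "slug", "snail", "thrips",
)


@dataclass(frozen=True)
class ClassRegistry:
    """Bijection between ordered class names and indices."""

    names: tuple[str, ...] = DEFAULT_CLASSES

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("class names must be unique")

    def __len__(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise KeyError(f"unknown class name {name!r}") from None

    def name(self, idx: int) -> str:
        if not 0 <= idx < len(self.names):
            raise KeyError(f"class index {idx} out of range [0, {len(self.names)})")
        return self.names[idx]


@dataclass(frozen=True)
class LabeledBox:
    """A class-labeled box; the unit of annotation."""

    box: Box
    class_id: int


@dataclass
class AnnotatedImage:
    """An 8-bit H x W x 3 image with its labeled boxes."""

    pixels: np.ndarray
    labels: list[LabeledBox] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError(f"pixels must be H x W x 3, got {self.pixels.shape}")
        h, w = self.pixels.shape[:2]
        if h < 1 or w < 1:
            raise ValueError("image must have positive size")
        for lb in self.labels:
            b = lb.box
            if not (0 <= b.x1 and b.x2 <= w and 0 <= b.y1 and b.y2 <= h):
                raise ValueError(
                    f"label box {b} outside image bounds {w}x{h} in {self.source_id!r}"
                )

    @property
    def height(self) -> int:
        return int(self.pixels.shape[0])

    @property
    def width(self) -> int:
        return int(self.pixels.shape[1])


@dataclass(frozen=True)
class ImageAnnotation:
    """Annotation metadata without pixel data (as stored in a VOC file)."""

    source_id: str
    width: int
    height: int
    labels: tuple[LabeledBox, ...]


def read_voc_xml(path, registry: ClassRegistry = ClassRegistry()) -> ImageAnnotation:
    """Parse one VOC 2007 XML annotation file.

    Raises ``ValueError`` with file and object context on missing
    bndbox fields, inverted corners, or class names absent from the
    registry.
    """
    path = Path(path)
    root = ET.parse(path).getroot()
    size = root.find("size")
    if size is None or size.find("width") is None or size.find("height") is None:
        raise ValueError(f"{path}: missing size element")
    width = int(size.findtext("width"))
    height = int(size.findtext("height"))
    filename = root.findtext("filename", default=path.stem)

    labels = []
    for i, obj in enumerate(root.iter("object")):
        name = obj.findtext("name")
        if name is None:
            raise ValueError(f"{path}: object {i} has no name")
        try:
            class_id = registry.index(name)
        except KeyError as e:
            raise ValueError(f"{path}: object {i}: {e.args[0]}") from None
        bnd = obj.find("bndbox")
        if bnd is None:
            raise ValueError(f"{path}: object {i} ({name}) has no bndbox")
        coords = {}
        for key in ("xmin", "ymin", "xmax", "ymax"):
            text = bnd.findtext(key)
            if text is None:
                raise ValueError(f"{path}: object {i} ({name}) missing {key}")
            coords[key] = float(text)
        if coords["xmax"] <= coords["xmin"] or coords["ymax"] <= coords["ymin"]:
            raise ValueError(
                f"{path}: object {i} ({name}) has inverted or empty box {coords}"
            )
        box = Box(coords["xmin"], coords["ymin"], coords["xmax"], coords["ymax"])
        labels.append(LabeledBox(box=box, class_id=class_id))
    return ImageAnnotation(
        source_id=filename, width=width, height=height, labels=tuple(labels)
    )


def write_voc_xml(
    ann: ImageAnnotation | AnnotatedImage,
    path,
    registry: ClassRegistry = ClassRegistry(),
) -> None:
    """Write an annotation as VOC 2007 XML, readable by :func:`read_voc_xml`."""
    root = ET.Element("annotation")
    ET.SubElement(root, "filename").text = ann.source_id
    size = ET.SubElement(root, "size")
    ET.SubElement(size, "width").text = str(ann.width)
    ET.SubElement(size, "height").text = str(ann.height)
    ET.SubElement(size, "depth").text = "3"
    for lb in ann.labels:
        obj = ET.SubElement(root, "object")
        ET.SubElement(obj, "name").text = registry.name(lb.class_id)
        bnd = ET.SubElement(obj, "bndbox")
        ET.SubElement(bnd, "xmin").text = repr(lb.box.x1)
        ET.SubElement(bnd, "ymin").text = repr(lb.box.y1)
        ET.SubElement(bnd, "xmax").text = repr(lb.box.x2)
        ET.SubElement(bnd, "ymax").text = repr(lb.box.y2)
    tree = ET.ElementTree(root)
    ET.indent(tree)
    tree.write(path, encoding="unicode")


def read_yolo_txt(path, image_size: tuple[int, int]) -> list[LabeledBox]:
    """Read YOLO-style labels: lines of ``class cx cy w h`` in [0, 1].

    ``image_size`` is (width, height) in pixels; coordinates convert to
    corner pixels via ``x1 = (cx - w/2) * W`` etc.  Normalized values
    outside [0, 1] are rejected.
    """
    w_img, h_img = image_size
    labels = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        class_id = int(parts[0])
        cx, cy, w, h = map(float, parts[1:])
        if not all(0.0 <= v <= 1.0 for v in (cx, cy, w, h)):
            raise ValueError(f"{path}:{ln}: normalized values out of [0,1]: {line!r}")
        box = Box(
            (cx - w / 2) * w_img,
            (cy - h / 2) * h_img,
            (cx + w / 2) * w_img,
            (cy + h / 2) * h_img,
        )
        labels.append(LabeledBox(box=box, class_id=class_id))
    return labels


def write_yolo_txt(labels: Iterable[LabeledBox], path, image_size: tuple[int, int]) -> None:
    w_img, h_img = image_size
    lines = []
    for lb in labels:
        b = lb.box
        cx = (b.x1 + b.x2) / 2 / w_img
        cy = (b.y1 + b.y2) / 2 / h_img
        lines.append(
            f"{lb.class_id} {cx:.6f} {cy:.6f} {b.width / w_img:.6f} {b.height / h_img:.6f}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


@dataclass(frozen=True)
class DatasetSplit:
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int


def _largest_remainder(n: int, fractions: Sequence[float]) -> list[int]:
    exact = [n * f for f in fractions]
    counts = [math.floor(e) for e in exact]
    short = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: (-(exact[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    return counts


def split_dataset(ids: Sequence[str], seed: int = 0) -> DatasetSplit:
    """Seeded two-stage partition into train/val/test (0.56/0.24/0.20)."""
    if len(ids) < 10:
        raise ValueError(f"need at least 10 ids to split, got {len(ids)}")
    n = len(ids)
    n_train, n_val, n_test = _largest_remainder(n, (0.8 * 0.7, 0.8 * 0.3, 0.2))
    rng = np.random.default_rng(seed)
    shuffled = [ids[i] for i in rng.permutation(n)]
    return DatasetSplit(
        train_ids=tuple(shuffled[:n_train]),
        val_ids=tuple(shuffled[n_train : n_train + n_val]),
        test_ids=tuple(shuffled[n_train + n_val :]),
        seed=seed,
    )


def discover_pairs(
    image_dir, label_dir, image_exts: Sequence[str] = (".jpg", ".jpeg", ".png")
) -> tuple[dict[str, tuple[Path, Path]], list[str]]:
    """Pair image and label files by filename stem.

    Returns (matched stem -> (image path, label path), unmatched stems).
    Unmatched stems are reported, never silently dropped.
    """
    images = {
        p.stem: p
        for p in sorted(Path(image_dir).iterdir())
        if p.suffix.lower() in image_exts
    }
    label_paths = {
        p.stem: p
        for p in sorted(Path(label_dir).iterdir())
        if p.suffix.lower() in (".xml", ".txt")
    }
    matched = {
        stem: (images[stem], label_paths[stem])
        for stem in sorted(images.keys() & label_paths.keys())
    }
    unmatched = sorted((images.keys() | label_paths.keys()) - matched.keys())
    return matched, unmatched
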