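"""Detection evaluation: greedy matching, P-R curves, AP/mAP, F1, mDT.

Evaluation is per class.  Within each image, detections of a class are
sorted by descending confidence and each is matched greedily to the
unmatched ground truth of highest IoU at or above the threshold
(PASCAL-style, default 0.5); a matched detection is a true positive,
an unmatched one a false positive, and any leftover ground truth a
false negative.  From the ranked TP/FP flags::

    P = TP / (TP + FP)        R = TP / n_gt

AP is the area under the precision-recall curve using all-point
interpolation (the monotone non-increasing precision envelope
integrated over recall); mAP is the arithmetic mean of per-class APs;
F1 = 2PR/(P+R) at a fixed confidence threshold; mDT is the mean
per-image detection time in seconds.

Ties in confidence are broken by stable input order (AP can differ at
ties, so the convention is fixed and documented here).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .boxes import Box, iou, normalize_box
from .dataset import ClassRegistry

__all__ = [
    "Detection",
    "GroundTruth",
    "PRCurve",
    "EvalReport",
    "match_detections",
    "precision_recall_curve",
    "average_precision",
    "mean_ap",
    "f1_score",
    "mean_detection_time",
    "evaluate",
    "read_detections_csv",
    "write_detections_csv",
]


@dataclass(frozen=True)
class Detection:
    """A confidence-scored, class-labeled box on one image."""

    image_id: str
    box: Box
    class_id: int
    confidence: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.confidence) and 0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must be finite in [0,1], got {self.confidence}")


@dataclass(frozen=True)
class GroundTruth:
    image_id: str
    box: Box
    class_id: int


@dataclass(frozen=True)
class PRCurve:
    """Precision/recall at each rank of the descending-confidence list."""

    recalls: tuple[float, ...]
    precisions: tuple[float, ...]


@dataclass(frozen=True)
class EvalReport:
    per_class_ap: dict[int, float]
    map: float
    per_class_precision: dict[int, float]
    per_class_recall: dict[int, float]
    per_class_f1: dict[int, float]
    mdt: float | None = None


def _sort_by_confidence(dets: Sequence[Detection]) -> list[Detection]:
    # stable descending sort: ties keep input order
    return sorted(dets, key=lambda d: -d.confidence)


def match_detections(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    iou_threshold: float = 0.5,
    class_id: int | None = None,
) -> tuple[list[Detection], np.ndarray, int, int]:
    """Greedy per-image matching for one class.

    Returns ``(sorted_dets, tp_flags, n_gt, n_fn)`` where ``tp_flags``
    aligns with ``sorted_dets`` (descending confidence).  Each
    detection matches at most one ground truth and vice versa.
    """
    if not 0.0 < iou_threshold <= 1.0:
        raise ValueError(f"iou_threshold must be in (0,1], got {iou_threshold}")
    if class_id is not None:
        dets = [d for d in dets if d.class_id == class_id]
        gts = [g for g in gts if g.class_id == class_id]

    gt_by_image: dict[str, list[GroundTruth]] = {}
    for g in gts:
        gt_by_image.setdefault(g.image_id, []).append(g)
    matched: dict[str, set[int]] = {img: set() for img in gt_by_image}

    sorted_dets = _sort_by_confidence(dets)
    flags = np.zeros(len(sorted_dets), dtype=bool)
    for i, det in enumerate(sorted_dets):
        candidates = gt_by_image.get(det.image_id, [])
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(candidates):
            if j in matched[det.image_id]:
                continue
            v = iou(det.box, g.box)
            if v > best_iou:
                best_j, best_iou = j, v
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[det.image_id].add(best_j)
            flags[i] = True

    n_gt = len(gts)
    n_fn = n_gt - int(flags.sum())
    return sorted_dets, flags, n_gt, n_fn


def precision_recall_curve(flags: Sequence[bool], n_gt: int) -> PRCurve:
    """Cumulative precision/recall over ranked TP/FP flags.

    ``flags`` must already be ordered by descending confidence.  With
    no ground truth the curve is empty (AP is 0 by convention).
    """
    flags = np.asarray(flags, dtype=bool)
    if n_gt < 1:
        return PRCurve(recalls=(), precisions=())
    if len(flags) == 0:
        return PRCurve(recalls=(), precisions=())
    tp = np.cumsum(flags)
    ranks = np.arange(1, len(flags) + 1)
    return PRCurve(
        recalls=tuple(tp / n_gt),
        precisions=tuple(tp / ranks),
    )


def average_precision(curve: PRCurve) -> float:
    """Area under the monotone precision envelope over recall.

    All-point interpolation: precision at each recall level is the
    maximum precision at any higher-or-equal rank recall, integrated
    over the recall increments.  An empty curve gives 0.
    """
    if len(curve.recalls) == 0:
        return 0.0
    r = np.concatenate([[0.0], np.asarray(curve.recalls)])
    p = np.concatenate([[0.0], np.asarray(curve.precisions)])
    # envelope: running max from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum((r[1:] - r[:-1]) * p[1:]))


def mean_ap(per_class_aps: Sequence[float] | Mapping[int, float]) -> float:
    """Arithmetic mean of per-class average precisions."""
    values = list(per_class_aps.values()) if isinstance(per_class_aps, Mapping) else list(per_class_aps)
    if not values:
        raise ValueError("mean_ap needs at least one class AP")
    return float(np.mean(values))


def f1_score(p: float, r: float) -> float:
    """Harmonic mean of precision and recall; 0 when both are 0."""
    if not (0.0 <= p <= 1.0 and 0.0 <= r <= 1.0):
        raise ValueError(f"precision/recall must be in [0,1], got {p}, {r}")
    if p + r == 0.0:
        return 0.0
    return 2.0 * p * r / (p + r)


def mean_detection_time(times_seconds: Sequence[float]) -> float:
    """Mean per-image detection time, seconds."""
    times = np.asarray(times_seconds, dtype=float)
    if times.size == 0:
        raise ValueError("mean_detection_time needs at least one measurement")
    if (times < 0).any():
        raise ValueError("detection times must be nonnegative")
    return float(times.mean())


def evaluate(
    dets: Sequence[Detection],
    gts: Sequence[GroundTruth],
    classes: Sequence[int],
    iou_threshold: float = 0.5,
    conf_threshold: float = 0.25,
    times_seconds: Sequence[float] | None = None,
) -> EvalReport:
    """Full per-class evaluation over the listed class ids.

    AP uses every detection regardless of confidence; precision,
    recall and F1 are reported at ``conf_threshold``.  Detections of a
    class not listed in ``classes`` are rejected.
    """
    known = set(classes)
    for d in dets:
        if d.class_id not in known:
            raise ValueError(
                f"detection on {d.image_id!r} has unknown class {d.class_id}"
            )

    per_ap: dict[int, float] = {}
    per_p: dict[int, float] = {}
    per_r: dict[int, float] = {}
    per_f1: dict[int, float] = {}
    for c in classes:
        _, flags, n_gt, _ = match_detections(dets, gts, iou_threshold, class_id=c)
        per_ap[c] = average_precision(precision_recall_curve(flags, n_gt))

        sorted_c, flags_c, n_gt_c, _ = match_detections(
            [d for d in dets if d.confidence >= conf_threshold],
            gts,
            iou_threshold,
            class_id=c,
        )
        tp = int(flags_c.sum())
        n_det = len(sorted_c)
        p = tp / n_det if n_det else 0.0
        r = tp / n_gt_c if n_gt_c else 0.0
        per_p[c], per_r[c], per_f1[c] = p, r, f1_score(p, r)

    return EvalReport(
        per_class_ap=per_ap,
        map=mean_ap(per_ap),
        per_class_precision=per_p,
        per_class_recall=per_r,
        per_class_f1=per_f1,
        mdt=mean_detection_time(times_seconds) if times_seconds is not None else None,
    )


# ---------------------------------------------------------------------------
# Detection file I/O
# ---------------------------------------------------------------------------

_CSV_COLUMNS = ["image_id", "class", "confidence", "x1", "y1", "x2", "y2"]


def read_detections_csv(
    path, registry: ClassRegistry | None = None
) -> list[Detection]:
    """Read detections from CSV (image_id,class,confidence,x1,y1,x2,y2).

    ``class`` may be a registry name (when a registry is given) or an
    integer id.
    """
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dets = []
    for image_id, cls, conf, x1, y1, x2, y2 in df[_CSV_COLUMNS].itertuples(
        index=False, name=None
    ):
        class_id = registry.index(str(cls)) if registry is not None else int(cls)
        dets.append(
            Detection(
                image_id=str(image_id),
                box=normalize_box(x1, y1, x2, y2),
                class_id=class_id,
                confidence=float(conf),
            )
        )
    return dets


def write_detections_csv(
    dets: Sequence[Detection], path, registry: ClassRegistry | None = None
) -> None:
    rows = [
        {
            "image_id": d.image_id,
            "class": registry.name(d.class_id) if registry is not None else d.class_id,
            "confidence": d.confidence,
            "x1": d.box.x1,
            "y1": d.box.y1,
            "x2": d.box.x2,
            "y2": d.box.y2,
        }
        for d in dets
    ]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def report_to_json(report: EvalReport, path, registry: ClassRegistry | None = None) -> None:
    def keyed(d: dict[int, float]) -> dict[str, float]:
        return {
            (registry.name(k) if registry is not None else str(k)): v
            for k, v in d.items()
        }

    payload = {
        "mAP": report.map,
        "per_class_ap": keyed(report.per_class_ap),
        "per_class_precision": keyed(report.per_class_precision),
        "per_class_recall": keyed(report.per_class_recall),
        "per_class_f1": keyed(report.per_class_f1),
    }
    if report.mdt is not None:
        payload["mDT_seconds"] = report.mdt
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")
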