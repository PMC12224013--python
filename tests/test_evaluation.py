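"""Matching, P-R curves, AP/mAP/F1/mDT, and the full evaluate report."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestkit.boxes import Box
from pestkit.dataset import ClassRegistry
from pestkit.evaluation import (
    Detection,
    GroundTruth,
    PRCurve,
    average_precision,
    evaluate,
    f1_score,
    match_detections,
    mean_ap,
    mean_detection_time,
    precision_recall_curve,
    read_detections_csv,
    write_detections_csv,
)
from pestkit.synthetic import gen_planted_eval


def brute_force_ap(flags, n_gt) -> float:
    """Definition-level oracle: interpolated precision at each achieved
    recall level via an explicit scan over every rank."""
    if n_gt < 1 or not len(flags):
        return 0.0
    tp = np.cumsum(flags)
    recall = tp / n_gt
    precision = tp / np.arange(1, len(flags) + 1)
    ap, prev = 0.0, 0.0
    for i, f in enumerate(flags):
        if not f:
            continue
        p_interp = max(precision[j] for j in range(len(flags)) if recall[j] >= recall[i])
        ap += (recall[i] - prev) * p_interp
        prev = recall[i]
    return ap


def det(img, box, cls, conf):
    return Detection(img, box, cls, conf)


def gt(img, box, cls):
    return GroundTruth(img, box, cls)


B = Box(0, 0, 50, 50)
B_NEAR = Box(2, 2, 52, 52)  # IoU ~ 0.85
B_FAR = Box(200, 200, 250, 250)


def test_match_single_true_positive():
    dets, flags, n_gt, fn = match_detections(
        [det("i", B_NEAR, 0, 0.9)], [gt("i", B, 0)], 0.5, class_id=0
    )
    assert flags.tolist() == [True] and n_gt == 1 and fn == 0


def test_match_single_gt_two_detections():
    """Only the higher-confidence detection claims the ground truth."""
    d = [det("i", B_NEAR, 0, 0.6), det("i", B, 0, 0.9)]
    sorted_d, flags, _, fn = match_detections(d, [gt("i", B, 0)], 0.5, class_id=0)
    assert [x.confidence for x in sorted_d] == [0.9, 0.6]
    assert flags.tolist() == [True, False] and fn == 0


def test_match_wrong_class_is_fp_and_fn():
    dets = [det("i", B, 1, 0.9)]
    gts = [gt("i", B, 0)]
    _, flags1, _, _ = match_detections(dets, gts, 0.5, class_id=1)
    assert flags1.tolist() == [False]  # FP for class 1
    _, flags0, n_gt0, fn0 = match_detections(dets, gts, 0.5, class_id=0)
    assert len(flags0) == 0 and n_gt0 == 1 and fn0 == 1  # FN for class 0


def test_match_is_per_image():
    dets = [det("a", B, 0, 0.9)]
    gts = [gt("b", B, 0)]
    _, flags, _, fn = match_detections(dets, gts, 0.5, class_id=0)
    assert flags.tolist() == [False] and fn == 1


def test_match_invalid_threshold_rejected():
    with pytest.raises(ValueError):
        match_detections([], [], iou_threshold=0.0)


def test_pr_curve_examples():
    assert precision_recall_curve([True], 1) == PRCurve((1.0,), (1.0,))
    curve = precision_recall_curve([True, False, True], 2)
    assert curve.recalls == pytest.approx((0.5, 0.5, 1.0))
    assert curve.precisions == pytest.approx((1.0, 0.5, 2 / 3))
    all_fp = precision_recall_curve([False, False], 3)
    assert all_fp.precisions == (0.0, 0.0) and all_fp.recalls == (0.0, 0.0)


def test_ap_examples():
    assert average_precision(precision_recall_curve([True], 1)) == 1.0
    assert average_precision(
        precision_recall_curve([True, False, True], 2)
    ) == pytest.approx(5 / 6)
    assert average_precision(precision_recall_curve([False] * 4, 2)) == 0.0
    assert average_precision(PRCurve((), ())) == 0.0


@given(
    flags=st.lists(st.booleans(), min_size=1, max_size=30),
    extra_gt=st.integers(0, 5),
)
@settings(derandomize=True, max_examples=200)
def test_ap_matches_brute_force_oracle(flags, extra_gt):
    n_gt = sum(flags) + extra_gt
    if n_gt == 0:
        return
    got = average_precision(precision_recall_curve(flags, n_gt))
    assert got == pytest.approx(brute_force_ap(flags, n_gt), abs=1e-9)


def test_ap_invariant_to_monotone_confidence_transform():
    """AP depends only on ranked flags, not confidence values."""
    planted = gen_planted_eval({0: [1, 0, 1, 1, 0]}, {0: 4}, seed=0)
    base_dets = list(planted.detections)
    squashed = [
        Detection(d.image_id, d.box, d.class_id, d.confidence**3)
        for d in base_dets
    ]
    for dets in (base_dets, squashed):
        _, flags, n_gt, _ = match_detections(dets, list(planted.ground_truths), 0.5, 0)
        assert average_precision(
            precision_recall_curve(flags, n_gt)
        ) == pytest.approx(planted.expected_ap[0])


def test_trailing_fp_never_increases_ap(rng):
    for _ in range(20):
        flags = list(rng.integers(0, 2, size=rng.integers(1, 15)).astype(bool))
        n_gt = int(sum(flags)) + int(rng.integers(0, 3))
        if n_gt == 0:
            continue
        base = average_precision(precision_recall_curve(flags, n_gt))
        worse = average_precision(precision_recall_curve(flags + [False], n_gt))
        assert worse <= base + 1e-12


def test_mean_ap():
    assert mean_ap([1.0]) == 1.0
    assert mean_ap([0.5, 1.0]) == 0.75
    assert mean_ap({c: 0.7 for c in range(12)}) == pytest.approx(0.7)
    with pytest.raises(ValueError):
        mean_ap([])


def test_f1_score():
    assert f1_score(0.5, 0.5) == 0.5
    assert f1_score(1.0, 0.0) == 0.0
    assert f1_score(0.8, 0.6) == pytest.approx(0.6857142857142857)
    # harmonic <= arithmetic mean
    for p, r in [(0.3, 0.9), (0.99, 0.01), (0.6, 0.6)]:
        assert f1_score(p, r) <= (p + r) / 2 + 1e-12


def test_mean_detection_time():
    assert mean_detection_time([0.0072] * 1200) == pytest.approx(0.0072)
    assert mean_detection_time([1, 2, 3]) == 2
    assert mean_detection_time([0.5]) == 0.5
    with pytest.raises(ValueError):
        mean_detection_time([])


def test_evaluate_perfect_detector():
    gts = [gt("i", Box(c * 100, 0, c * 100 + 40, 40), c) for c in range(3)]
    dets = [det(g.image_id, g.box, g.class_id, 1.0) for g in gts]
    report = evaluate(dets, gts, classes=[0, 1, 2])
    assert report.map == 1.0
    assert all(v == 1.0 for v in report.per_class_f1.values())


def test_evaluate_no_detections():
    gts = [gt("i", B, 0)]
    report = evaluate([], gts, classes=[0])
    assert report.map == 0.0
    assert report.per_class_recall[0] == 0.0


def test_evaluate_unknown_class_rejected():
    with pytest.raises(ValueError):
        evaluate([det("i", B, 5, 0.9)], [], classes=[0, 1])


def test_evaluate_reproduces_planted_report():
    planted = gen_planted_eval(
        {0: [1, 0, 1], 1: [1, 1, 0, 0], 2: [0, 0]},
        {0: 2, 1: 2, 2: 1},
        seed=3,
    )
    report = evaluate(
        list(planted.detections), list(planted.ground_truths), classes=[0, 1, 2]
    )
    for c, expected in planted.expected_ap.items():
        assert report.per_class_ap[c] == pytest.approx(expected, abs=1e-12)
    assert report.map == pytest.approx(planted.expected_map, abs=1e-12)


def test_evaluate_reports_mdt():
    report = evaluate([], [gt("i", B, 0)], classes=[0], times_seconds=[0.01, 0.02])
    assert report.mdt == pytest.approx(0.015)


def test_detections_csv_roundtrip(tmp_path):
    reg = ClassRegistry()
    dets = [
        det("img1", Box(1, 2, 3, 4), reg.index("snail"), 0.75),
        det("img2", Box(10, 20, 30, 40), reg.index("thrips"), 0.5),
    ]
    path = tmp_path / "dets.csv"
    write_detections_csv(dets, path, reg)
    assert read_detections_csv(path, reg) == dets
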