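"""Point-line-distance IoU (PLDIoU) bounding-box regression loss.

The PLDIoU score augments plain IoU with a geometric penalty: draw the
line ``l`` through the centers of the predicted box C and the target
box G, and measure the squared distance ``d^2`` from the center of
their minimum enclosing box A to ``l``::

    PLDIoU      = IoU - eta * R,      R = d^2
    L_PLDIoU    = 1 - IoU + eta * R   (the loss)

When the three centers are collinear — in particular whenever C and G
have equal width and height, since then A's center is the midpoint of
the two centers — the penalty vanishes and the loss reduces to the
plain IoU loss.

The raw penalty is in squared pixels (the published form, with the
weight ``eta`` defaulting to 10).  An opt-in normalized variant divides
R by the squared diagonal of the enclosing box, making the penalty
scale-invariant and bounded; see :class:`LossConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .boxes import (
    Box,
    box_center,
    iou,
    line_through,
    min_enclosing_box,
    point_line_penalty,
)

__all__ = [
    "LossConfig",
    "pldiou_penalty",
    "pldiou",
    "pldiou_loss",
    "batch_pldiou_loss",
    "pldiou_loss_grad",
]


@dataclass(frozen=True)
class LossConfig:
    """Penalty weight and normalization mode for the PLDIoU family.

    eta : nonnegative weight on the point-line penalty (default 10).
    normalize_penalty : if True, divide the squared distance by the
        squared diagonal of the minimum enclosing box (DIoU-style),
        yielding a scale-invariant penalty in [0, 1/4]; if False the
        penalty is in raw squared pixels.
    """

    eta: float = 10.0
    normalize_penalty: bool = False

    def __post_init__(self) -> None:
        if not (self.eta >= 0.0):
            raise ValueError(f"eta must be nonnegative, got {self.eta}")


def pldiou_penalty(c: Box, g: Box, cfg: LossConfig = LossConfig()) -> float:
    """Penalty term R: squared center-to-line distance, >= 0.

    Zero exactly when the centers of C, G and their enclosing box are
    collinear (always true for equal-sized boxes) or coincide.
    """
    line = line_through(box_center(c), box_center(g))
    r = point_line_penalty(line, box_center(min_enclosing_box(c, g)))
    if cfg.normalize_penalty:
        a = min_enclosing_box(c, g)
        diag2 = a.width**2 + a.height**2
        r = r / diag2 if diag2 > 0.0 else 0.0
    return r


def pldiou(c: Box, g: Box, cfg: LossConfig = LossConfig()) -> float:
    """PLDIoU score: ``iou(c, g) - eta * R``.  Always <= iou(c, g)."""
    return iou(c, g) - cfg.eta * pldiou_penalty(c, g, cfg)


def pldiou_loss(c: Box, g: Box, cfg: LossConfig = LossConfig()) -> float:
    """PLDIoU loss: ``1 - iou + eta * R``.  Always >= the IoU loss."""
    return 1.0 - iou(c, g) + cfg.eta * pldiou_penalty(c, g, cfg)


def batch_pldiou_loss(
    pairs: Sequence[tuple[Box, Box]], cfg: LossConfig = LossConfig()
) -> list[float]:
    """Elementwise :func:`pldiou_loss` over (prediction, target) pairs."""
    return [pldiou_loss(c, g, cfg) for c, g in pairs]


# ---------------------------------------------------------------------------
# Analytic gradient
# ---------------------------------------------------------------------------

def pldiou_loss_grad(c: Box, g: Box, cfg: LossConfig = LossConfig()) -> np.ndarray:
    """Gradient of :func:`pldiou_loss` w.r.t. the eight box corners.

    Order: (cx1, cy1, cx2, cy2, gx1, gy1, gx2, gy2).  The loss is
    piecewise smooth; at the measure-zero kinks (corner ties, box
    boundary contact, coincident centers) the C-side subgradient branch
    is returned.
    """
    grad = -_iou_grad(c, g)
    if cfg.eta != 0.0:
        grad = grad + cfg.eta * _penalty_grad(c, g, cfg.normalize_penalty)
    return grad


def _iou_grad(c: Box, g: Box) -> np.ndarray:
    dareaC = np.array([-c.height, -c.width, c.height, c.width, 0, 0, 0, 0], float)
    dareaG = np.array([0, 0, 0, 0, -g.height, -g.width, g.height, g.width], float)

    iw = min(c.x2, g.x2) - max(c.x1, g.x1)
    ih = min(c.y2, g.y2) - max(c.y1, g.y1)
    dI = np.zeros(8)
    inter = 0.0
    if iw > 0.0 and ih > 0.0:
        inter = iw * ih
        # ties resolved toward the prediction box's branch
        if c.x1 >= g.x1:
            dI[0] = -ih
        else:
            dI[4] = -ih
        if c.x2 <= g.x2:
            dI[2] = ih
        else:
            dI[6] = ih
        if c.y1 >= g.y1:
            dI[1] = -iw
        else:
            dI[5] = -iw
        if c.y2 <= g.y2:
            dI[3] = iw
        else:
            dI[7] = iw

    union = c.area + g.area - inter
    if union <= 0.0:
        return np.zeros(8)
    dU = dareaC + dareaG - dI
    return (dI * union - inter * dU) / union**2


def _penalty_grad(c: Box, g: Box, normalized: bool) -> np.ndarray:
    px, py = (c.x1 + c.x2) / 2.0, (c.y1 + c.y2) / 2.0
    qx, qy = (g.x1 + g.x2) / 2.0, (g.y1 + g.y2) / 2.0
    ax1, ay1 = min(c.x1, g.x1), min(c.y1, g.y1)
    ax2, ay2 = max(c.x2, g.x2), max(c.y2, g.y2)
    ax, ay = (ax1 + ax2) / 2.0, (ay1 + ay2) / 2.0

    alpha, beta = qy - py, qx - px
    den = alpha * alpha + beta * beta
    if den == 0.0:
        return np.zeros(8)
    lam = qx * py - px * qy
    num = alpha * ax - beta * ay + lam
    r = num * num / den

    # dR w.r.t. the six center coordinates (px, py, qx, qy, ax, ay)
    dnum = np.array([ay - qy, qx - ax, py - ay, ax - px, alpha, -beta])
    dden = np.array([-2 * beta, -2 * alpha, 2 * beta, 2 * alpha, 0.0, 0.0])
    dr_ctr = (2 * num * dnum) / den - (num * num / den**2) * dden

    # chain centers -> corners; ties toward the prediction box's branch
    jac = np.zeros((6, 8))
    jac[0, 0] = jac[0, 2] = 0.5  # px
    jac[1, 1] = jac[1, 3] = 0.5  # py
    jac[2, 4] = jac[2, 6] = 0.5  # qx
    jac[3, 5] = jac[3, 7] = 0.5  # qy
    jac[4, 0 if c.x1 <= g.x1 else 4] += 0.5  # ax via min corner
    jac[4, 2 if c.x2 >= g.x2 else 6] += 0.5  # ax via max corner
    jac[5, 1 if c.y1 <= g.y1 else 5] += 0.5
    jac[5, 3 if c.y2 >= g.y2 else 7] += 0.5
    dr = dr_ctr @ jac

    if not normalized:
        return dr

    s = (ax2 - ax1) ** 2 + (ay2 - ay1) ** 2
    if s == 0.0:
        return np.zeros(8)
    ds = np.zeros(8)
    ds[0 if c.x1 <= g.x1 else 4] = -2 * (ax2 - ax1)
    ds[2 if c.x2 >= g.x2 else 6] = 2 * (ax2 - ax1)
    ds[1 if c.y1 <= g.y1 else 5] = -2 * (ay2 - ay1)
    ds[3 if c.y2 >= g.y2 else 7] = 2 * (ay2 - ay1)
    return (dr * s - r * ds) / s**2
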