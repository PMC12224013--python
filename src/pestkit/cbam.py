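"""Convolutional Block Attention Module (CBAM) on C x H x W arrays.

CBAM refines a feature map F in two sequential multiplicative stages::

    F'  = Mc(F)  * F     (channel attention, Mc: C x 1 x 1)
    F'' = Ms(F') * F'    (spatial attention, Ms: 1 x H x W)

Channel attention pools F over all spatial positions (average and max),
passes both pooled vectors through a shared two-layer bottleneck MLP
(C -> C/r -> C, ReLU in between, no biases), sums, and applies a
sigmoid.  Spatial attention pools across channels, stacks the two H x W
maps, convolves with a single 7 x 7 kernel (zero padding 3, so H and W
are preserved) and applies a sigmoid.  Both attention maps therefore
lie strictly in (0, 1), and the refined output never exceeds the input
in magnitude elementwise.

This is a NumPy reference implementation intended for analysis and
testing of the attention transform itself; it does not train weights.
The "4-stream" helper applies four independently parameterized CBAM
blocks to the four feature streams of a detection neck.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import correlate

__all__ = [
    "ChannelAttentionParams",
    "SpatialAttentionParams",
    "channel_attention",
    "spatial_attention",
    "cbam",
    "apply_4cbam",
    "init_cbam_params",
    "save_params",
    "load_params",
]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class ChannelAttentionParams:
    """Shared-MLP weights for channel attention.

    w0 maps C -> C/r (reduction), w1 maps C/r -> C (expansion);
    r must divide C.
    """

    w0: np.ndarray
    w1: np.ndarray
    r: int

    def __post_init__(self) -> None:
        c_red, c = self.w0.shape
        if self.w1.shape != (c, c_red):
            raise ValueError(
                f"w1 shape {self.w1.shape} inconsistent with w0 {self.w0.shape}"
            )
        if self.r < 1 or c % self.r != 0 or c // self.r != c_red:
            raise ValueError(f"reduction r={self.r} incompatible with C={c}")

    @property
    def channels(self) -> int:
        return self.w0.shape[1]


@dataclass(frozen=True)
class SpatialAttentionParams:
    """7x7 convolution over the stacked [avg; max] channel pools."""

    kernel: np.ndarray  # shape (1, 2, 7, 7)
    bias: float = 0.0
    pool_order: tuple[str, str] = ("avg", "max")

    def __post_init__(self) -> None:
        if self.kernel.shape != (1, 2, 7, 7):
            raise ValueError(f"kernel must be (1,2,7,7), got {self.kernel.shape}")
        if sorted(self.pool_order) != ["avg", "max"]:
            raise ValueError(f"pool_order must permute ('avg','max'), got {self.pool_order}")


def _check_feature_map(f: np.ndarray) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3 or min(f.shape) < 1:
        raise ValueError(f"feature map must be C x H x W with positive dims, got {f.shape}")
    return f


def channel_attention(f: np.ndarray, p: ChannelAttentionParams) -> np.ndarray:
    """Per-channel weights Mc, shape (C, 1, 1), values in (0, 1)."""
    f = _check_feature_map(f)
    c = f.shape[0]
    if c != p.channels:
        raise ValueError(f"feature map has {c} channels, params expect {p.channels}")

    def mlp(v: np.ndarray) -> np.ndarray:
        return p.w1 @ np.maximum(p.w0 @ v, 0.0)

    avg = f.mean(axis=(1, 2))
    mx = f.max(axis=(1, 2))
    return _sigmoid(mlp(avg) + mlp(mx)).reshape(c, 1, 1)


def spatial_attention(f: np.ndarray, p: SpatialAttentionParams) -> np.ndarray:
    """Spatial weights Ms, shape (1, H, W), values in (0, 1)."""
    f = _check_feature_map(f)
    pools = {"avg": f.mean(axis=0), "max": f.max(axis=0)}
    stack = np.stack([pools[k] for k in p.pool_order])  # (2, H, W)
    padded = np.pad(stack, ((0, 0), (3, 3), (3, 3)))
    # conv-layer convention: cross-correlation, summed over input channels
    out = correlate(padded, p.kernel[0], mode="valid")[0]
    return _sigmoid(out + p.bias)[None, :, :]


def cbam(
    f: np.ndarray, cp: ChannelAttentionParams, sp: SpatialAttentionParams
) -> np.ndarray:
    """Channel-then-spatial refined feature map; shape equals input."""
    f = _check_feature_map(f)
    f_prime = channel_attention(f, cp) * f
    return spatial_attention(f_prime, sp) * f_prime


def apply_4cbam(
    streams: Sequence[np.ndarray],
    params: Sequence[tuple[ChannelAttentionParams, SpatialAttentionParams]],
) -> list[np.ndarray]:
    """Apply four independent CBAM blocks to four feature streams."""
    if len(streams) != 4 or len(params) != 4:
        raise ValueError(
            f"expected exactly 4 streams and 4 parameter pairs, got "
            f"{len(streams)} and {len(params)}"
        )
    return [cbam(f, cp, sp) for f, (cp, sp) in zip(streams, params)]


def init_cbam_params(
    channels: int, r: int = 16, seed: int = 0
) -> tuple[ChannelAttentionParams, SpatialAttentionParams]:
    """Deterministic untrained parameters, uniform in [-0.1, 0.1].

    r defaults to the conventional reduction ratio 16 and must divide
    ``channels``.
    """
    if channels % r != 0:
        raise ValueError(f"r={r} must divide channels={channels}")
    rng = np.random.default_rng(seed)
    c_red = channels // r
    cp = ChannelAttentionParams(
        w0=rng.uniform(-0.1, 0.1, (c_red, channels)),
        w1=rng.uniform(-0.1, 0.1, (channels, c_red)),
        r=r,
    )
    sp = SpatialAttentionParams(
        kernel=rng.uniform(-0.1, 0.1, (1, 2, 7, 7)),
        bias=float(rng.uniform(-0.1, 0.1)),
    )
    return cp, sp


def save_params(
    path, cp: ChannelAttentionParams, sp: SpatialAttentionParams
) -> None:
    np.savez(
        path,
        w0=cp.w0,
        w1=cp.w1,
        r=np.array(cp.r),
        kernel=sp.kernel,
        bias=np.array(sp.bias),
        pool_order=np.array(sp.pool_order),
    )


def load_params(path) -> tuple[ChannelAttentionParams, SpatialAttentionParams]:
    with np.load(path) as z:
        cp = ChannelAttentionParams(w0=z["w0"], w1=z["w1"], r=int(z["r"]))
        sp = SpatialAttentionParams(
            kernel=z["kernel"],
            bias=float(z["bias"]),
            pool_order=tuple(z["pool_order"]),
        )
    return cp, sp
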