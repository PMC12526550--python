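"""Feature-enhancement blocks: channel shuffle, SGAM and CAM.

All blocks are shape-preserving transforms on (C, H, W) feature maps
(batched as (N, C, H, W) internally).  SGAM applies channel attention
(per-location fully connected squeeze/excite across channels) followed
by spatial attention (two 7x7 convolutions) whose attention map is
channel-shuffled before gating.  CAM scores spatial context with a 1x1
convolution + per-channel spatial softmax and re-weights features through
a conv -> layer-norm -> conv -> sigmoid transform, added residually.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .nn import tensor as T
from .nn.tensor import Tensor

__all__ = [
    "shuffle_permutation", "channel_shuffle", "ChannelAttention",
    "SpatialAttention", "SGAM", "CAM", "build_block",
    "sgam_channel_attention", "sgam_spatial_attention", "sgam_forward",
    "cam_forward",
]


def shuffle_permutation(c: int, g: int) -> np.ndarray:
    """Channel permutation of a (g, c//g) reshape-transpose-flatten shuffle.

    perm[k] gives the input channel that lands at output position k.
    """
    if g < 1:
        raise ValueError(f"group count must be >= 1, got {g}")
    if c % g != 0:
        raise ValueError(f"group count {g} does not divide channel count {c}")
    return np.arange(c).reshape(g, c // g).T.ravel()


def channel_shuffle(x, g: int):
    """Shuffle channels of a (C,H,W) / (N,C,H,W) tensor or ndarray."""
    arr = x.data if isinstance(x, Tensor) else np.asarray(x)
    axis = arr.ndim - 3
    if axis not in (0, 1):
        raise ValueError("expected a 3-D (C,H,W) or 4-D (N,C,H,W) input")
    perm = shuffle_permutation(arr.shape[axis], g)
    if isinstance(x, Tensor):
        idx = (slice(None), perm) if axis == 1 else (perm,)
        return x[idx]
    return np.take(arr, perm, axis=axis)


def _as_batched(x):
    t = T.astensor(x)
    if t.ndim == 3:
        return t.reshape((1,) + t.shape), True
    if t.ndim == 4:
        return t, False
    raise ValueError("feature map must be 3-D or 4-D")


def _maybe_unbatch(t, squeeze):
    return t.reshape(t.shape[1:]) if squeeze else t


class ChannelAttention(nn.Module):
    """Per-location channel attention: sigmoid(W2 . relu(W1 . x_c))."""

    def __init__(self, c: int, ratio: int = 4, rng=None, dtype=np.float32):
        super().__init__()
        if ratio < 1:
            raise ValueError("reduction ratio must be >= 1")
        self.c = c
        self.cr = max(1, c // ratio)
        self.fc1 = nn.Linear(c, self.cr, rng=rng, dtype=dtype)
        self.fc2 = nn.Linear(self.cr, c, rng=rng, dtype=dtype)

    def attention(self, x):
        x, squeeze = _as_batched(x)
        if x.shape[1] != self.c:
            raise ValueError(
                f"channel mismatch: block built for C={self.c}, got {x.shape[1]}")
        # permute C,H,W -> H,W,C so the FC layers act on the channel axis
        perm = x.transpose((0, 2, 3, 1))
        hidden = T.relu(self.fc1(perm))
        ac = T.sigmoid(self.fc2(hidden))          # (N, H, W, C)
        ac_chw = ac.transpose((0, 3, 1, 2))       # permute back
        out = x * ac_chw
        return _maybe_unbatch(ac_chw, squeeze), _maybe_unbatch(out, squeeze)

    def forward(self, x):
        return self.attention(x)[1]


class SpatialAttention(nn.Module):
    """7x7-conv spatial attention finished with a channel shuffle."""

    def __init__(self, c: int, ratio: int = 4, groups: int = 2, k: int = 7,
                 rng=None, dtype=np.float32):
        super().__init__()
        if k != 7:
            raise ValueError("spatial attention requires 7x7 convolutions")
        if groups < 1 or c % groups != 0:
            raise ValueError(f"group count {groups} must divide C={c}")
        self.c = c
        self.groups = groups
        cr = max(1, c // ratio)
        self.conv1 = nn.Conv2d(c, cr, 7, padding=3, rng=rng, dtype=dtype)
        self.bn = nn.BatchNorm2d(cr, dtype=dtype)
        self.conv2 = nn.Conv2d(cr, c, 7, padding=3, rng=rng, dtype=dtype)

    def attention(self, x):
        x, squeeze = _as_batched(x)
        if x.shape[1] != self.c:
            raise ValueError(
                f"channel mismatch: block built for C={self.c}, got {x.shape[1]}")
        # order as written: conv1 -> ReLU -> BN -> conv2 -> sigmoid
        a = self.conv1(x)
        a = T.relu(a)
        a = self.bn(a)
        a = self.conv2(a)
        a_s = T.sigmoid(a)
        out = x * channel_shuffle(a_s, self.groups)
        return _maybe_unbatch(a_s, squeeze), _maybe_unbatch(out, squeeze)

    def forward(self, x):
        return self.attention(x)[1]


class SGAM(nn.Module):
    """Shuffle global attention: channel attention then spatial attention."""

    def __init__(self, c: int, ratio: int = 4, groups: int = 2,
                 rng=None, dtype=np.float32):
        super().__init__()
        self.ca = ChannelAttention(c, ratio, rng=rng, dtype=dtype)
        self.sa = SpatialAttention(c, ratio, groups, rng=rng, dtype=dtype)

    def forward(self, x):
        return self.sa(self.ca(x))


class CAM(nn.Module):
    """Context-aware residual block.

    Dataflow: 1x1 conv -> spatial softmax per channel -> elementwise
    multiply with the input (weighted map Xw) -> 1x1 conv -> LayerNorm ->
    1x1 conv -> sigmoid -> multiply with Xw -> add to the input.
    """

    def __init__(self, c: int, ratio: int = 4, rng=None, dtype=np.float32):
        super().__init__()
        self.c = c
        cb = max(1, c // ratio)
        self.conv_ctx = nn.Conv2d(c, c, 1, rng=rng, dtype=dtype)
        self.conv_a = nn.Conv2d(c, cb, 1, rng=rng, dtype=dtype)
        self.ln = nn.LayerNorm(cb, dtype=dtype)
        self.conv_b = nn.Conv2d(cb, c, 1, rng=rng, dtype=dtype)

    def forward(self, x):
        x, squeeze = _as_batched(x)
        if x.shape[1] != self.c:
            raise ValueError(
                f"channel mismatch: block built for C={self.c}, got {x.shape[1]}")
        n, c, h, w = x.shape
        scores = self.conv_ctx(x)
        # softmax over the H*W spatial positions within each channel
        weights = T.softmax(scores.reshape((n, c, h * w)), axis=-1)
        weights = weights.reshape((n, c, h, w))
        xw = weights * x
        gate = T.sigmoid(self.conv_b(self.ln(self.conv_a(xw))))
        out = x + gate * xw
        return _maybe_unbatch(out, squeeze)

    def spatial_softmax(self, x):
        """Expose the normalized context map (sums to 1 per channel slice)."""
        x, squeeze = _as_batched(x)
        n, c, h, w = x.shape
        scores = self.conv_ctx(x)
        weights = T.softmax(scores.reshape((n, c, h * w)), axis=-1)
        return _maybe_unbatch(weights.reshape((n, c, h, w)), squeeze)


def build_block(config: dict, c: int, rng=None, dtype=np.float32) -> nn.Module:
    """Construct an attention block from a plain config mapping."""
    kind = config.get("type")
    ratio = int(config.get("ratio", 4))
    if kind == "cam":
        return CAM(c, ratio=ratio, rng=rng, dtype=dtype)
    if kind == "sgam":
        return SGAM(c, ratio=ratio, groups=int(config.get("groups", 2)),
                    rng=rng, dtype=dtype)
    raise ValueError(f"unknown attention block type {kind!r}")


# -- functional wrappers (operate on and return plain arrays) -------------

def sgam_channel_attention(x, block: ChannelAttention):
    ac, out = block.attention(T.astensor(np.asarray(x, dtype=float)))
    return ac.data, out.data


def sgam_spatial_attention(xca, block: SpatialAttention):
    a_s, out = block.attention(T.astensor(np.asarray(xca, dtype=float)))
    return a_s.data, out.data


def sgam_forward(x, block: SGAM):
    return block(T.astensor(np.asarray(x, dtype=float))).data


def cam_forward(x, block: CAM):
    return block(T.astensor(np.asarray(x, dtype=float))).data
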