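"""Computational blocks: dense/residual blocks, channel attention, bottleneck.

The decoder's aggregation channel attention unit (ACAU) combines two kinds of
channel attention:

* squeeze-and-excitation on the low-level skip features ``x_l``:
  ``v_l = GAP(x_l)``, ``v_o = sigmoid(W2 relu(W1 v_l))``, ``y_l = v_o * x_l``;
* a generalized-mean (GeM) descriptor of the high-level features ``x_h``,
  channel-matched by a 1x1 convolution and rectified so the ``pk``-th power
  is defined, then ``x_out = sigmoid(v_h) * y_l``.

GeM pooling ``v_hc = (mean_i x_hc(i)^pk)^(1/pk)`` interpolates between average
pooling (``pk = 1``) and max pooling (``pk -> inf``).

The bottleneck follows the dense-atrous-convolution (DAC) plus residual
multi-kernel pooling (RMP) design: parallel dilated 3x3 branches summed onto a
residual path, and multi-size max-pool branches reduced to one channel each
and concatenated back to the input.
"""

from __future__ import annotations

import numpy as np

from .grad import Tensor, concat
from .grad import functional as F
from .grad import nn

__all__ = [
    "squeeze_gap",
    "excitation_gate",
    "squeeze_excite",
    "gem_pool",
    "SqueezeExcite",
    "DenseLayer",
    "DenseBlock",
    "Transition",
    "ResidualBlock",
    "ACAUBlock",
    "DAC",
    "RMP",
]


# --------------------------------------------------------------------- functional

def squeeze_gap(x: Tensor | np.ndarray) -> Tensor:
    """Global average pooling: squeeze (N,C,H,W) to one value per channel (N,C)."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    return x.mean(axis=(2, 3))


def excitation_gate(v: Tensor | np.ndarray, w1: Tensor | np.ndarray,
                    w2: Tensor | np.ndarray) -> Tensor:
    """Two-layer channel gate ``sigmoid(W2 relu(W1 v))`` with outputs in (0,1).

    ``v`` is (N,C) or (C,); ``w1`` maps C -> C/r and ``w2`` maps C/r -> C.
    """
    v = v if isinstance(v, Tensor) else Tensor(v)
    w1 = w1 if isinstance(w1, Tensor) else Tensor(w1)
    w2 = w2 if isinstance(w2, Tensor) else Tensor(w2)
    c = v.shape[-1]
    if w1.shape[1] != c or w2.shape[0] != c or w1.shape[0] != w2.shape[1]:
        raise ValueError(
            f"gate weights {w1.shape}x{w2.shape} do not map {c} channels "
            "through a shared bottleneck"
        )
    hidden = (v @ w1.transpose()).relu()
    return (hidden @ w2.transpose()).sigmoid()


def squeeze_excite(x: Tensor | np.ndarray, w1, w2) -> Tensor:
    """Re-weight the channels of ``x`` by its squeeze-and-excitation gate."""
    x = x if isinstance(x, Tensor) else Tensor(x)
    gate = excitation_gate(squeeze_gap(x), w1, w2)
    n, c = gate.shape
    return x * gate.reshape(n, c, 1, 1)


def gem_pool(x: Tensor | np.ndarray, pk: float, eps: float = 1e-12) -> Tensor:
    """Generalized-mean pooling of (N,C,H,W) to (N,C).

    Requires ``pk >= 1`` and, for non-integer ``pk``, a non-negative input
    (the fractional power is otherwise undefined); networks guarantee this by
    rectifying before pooling.  ``pk = 1`` reduces exactly to average pooling.
    """
    x = x if isinstance(x, Tensor) else Tensor(x)
    pk = float(pk)
    if pk < 1:
        raise ValueError(f"GeM exponent pk must be >= 1, got {pk}")
    if pk != int(pk) and np.any(x.data < 0):
        raise ValueError("GeM pooling with non-integer pk requires non-negative input")
    if pk == 1.0:
        return x.mean(axis=(2, 3))
    # rescale by the per-channel max so x^pk cannot overflow at large pk;
    # GeM is homogeneous of degree 1, so holding the scale constant during
    # backprop still yields the exact gradient (Euler's theorem)
    scale = np.maximum(np.abs(x.data).max(axis=(2, 3), keepdims=True), eps)
    scaled = x * (1.0 / scale)
    pooled = ((scaled**pk).mean(axis=(2, 3)) + eps) ** (1.0 / pk)
    return pooled * scale[:, :, 0, 0]


# ----------------------------------------------------------------------- modules

class SqueezeExcite(nn.Module):
    """Squeeze-and-excitation channel attention with reduction ratio ``r``."""

    def __init__(self, channels: int, reduction: int, *, rng: np.random.Generator):
        super().__init__()
        if channels % reduction:
            raise ValueError(
                f"SE reduction {reduction} does not divide {channels} channels"
            )
        self.fc1 = nn.Linear(channels, channels // reduction, bias=False, rng=rng)
        self.fc2 = nn.Linear(channels // reduction, channels, bias=False, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        return excitation_gate(squeeze_gap(x), self.fc1.weight, self.fc2.weight)

    def forward(self, x: Tensor) -> Tensor:
        g = self.gate(x)
        n, c = g.shape
        return x * g.reshape(n, c, 1, 1)


def _norm(kind: str, channels: int) -> nn.Module:
    if kind == "instance":
        return nn.InstanceNorm2d(channels)
    if kind == "batch":
        return nn.BatchNorm2d(channels)
    return nn.Identity()


class DenseLayer(nn.Module):
    """norm-ReLU-1x1 bottleneck, norm-ReLU-3x3 producing ``growth`` channels."""

    def __init__(self, in_channels: int, growth: int, bn_size: int, norm: str,
                 *, rng: np.random.Generator):
        super().__init__()
        inter = bn_size * growth
        self.body = nn.Sequential(
            _norm(norm, in_channels),
            nn.ReLU(),
            nn.Conv2d(in_channels, inter, 1, bias=False, rng=rng),
            _norm(norm, inter),
            nn.ReLU(),
            nn.Conv2d(inter, growth, 3, padding=1, bias=False, rng=rng),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class DenseBlock(nn.Module):
    """Densely connected block: layer ``l`` sees ``[u_0, ..., u_{l-1}]``.

    Output channel count is exactly ``in_channels + n_layers * growth``.
    """

    def __init__(self, in_channels: int, n_layers: int, growth: int,
                 bn_size: int = 4, norm: str = "batch", *, rng: np.random.Generator):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = in_channels + n_layers * growth
        for i in range(n_layers):
            setattr(self, f"layer{i}",
                    DenseLayer(in_channels + i * growth, growth, bn_size, norm, rng=rng))
        self.n_layers = n_layers

    def forward(self, x: Tensor) -> Tensor:
        if x.shape[1] != self.in_channels:
            raise ValueError(
                f"dense block built for {self.in_channels} channels, got {x.shape[1]}"
            )
        features = [x]
        for i in range(self.n_layers):
            layer: DenseLayer = getattr(self, f"layer{i}")
            features.append(layer(concat(features, axis=1)))
        return concat(features, axis=1)


class Transition(nn.Module):
    """Channel compression (1x1 conv) followed by 2x2 average-pool downsampling."""

    def __init__(self, in_channels: int, out_channels: int, norm: str = "batch",
                 *, rng: np.random.Generator):
        super().__init__()
        self.out_channels = out_channels
        self.body = nn.Sequential(
            _norm(norm, in_channels),
            nn.ReLU(),
            nn.Conv2d(in_channels, out_channels, 1, bias=False, rng=rng),
            nn.AvgPool2d(2),
        )

    def forward(self, x: Tensor) -> Tensor:
        return self.body(x)


class ResidualBlock(nn.Module):
    """Identity skip around an arbitrary shape-preserving inner module."""

    def __init__(self, inner: nn.Module):
        super().__init__()
        self.inner = inner

    def forward(self, x: Tensor) -> Tensor:
        h = self.inner(x)
        if h.shape != x.shape:
            raise ValueError(
                f"residual inner module changed shape {x.shape} -> {h.shape}"
            )
        return h + x


class ACAUBlock(nn.Module):
    """Aggregation channel attention upsampling (one decoder stage).

    ``x_high`` (coarse, from the previous decoder stage or the bottleneck) is
    1x1-convolved to the skip width, rectified, GeM-pooled and sigmoid-gated;
    the gate multiplies the SE-reweighted skip ``x_low``.  The gated skip is
    concatenated with the 2x-upsampled high-level path and fused by a 3x3
    convolution to ``out_channels``.  Output resolution equals ``x_low``'s
    (= 2x ``x_high``'s).
    """

    def __init__(self, low_channels: int, high_channels: int, out_channels: int,
                 se_reduction: int, pk: float, upsample: str = "deconv",
                 norm: str = "batch", *, rng: np.random.Generator):
        super().__init__()
        self.pk = float(pk)
        self.upsample_mode = upsample
        self.se = SqueezeExcite(low_channels, se_reduction, rng=rng)
        self.match = nn.Conv2d(high_channels, low_channels, 1, rng=rng)
        if upsample == "deconv":
            self.up = nn.ConvTranspose2d(high_channels, low_channels, 2, stride=2, rng=rng)
        else:
            self.up = nn.Conv2d(high_channels, low_channels, 1, rng=rng)
        self.fuse = nn.Sequential(
            nn.Conv2d(2 * low_channels, out_channels, 3, padding=1, bias=False, rng=rng),
            _norm(norm, out_channels),
            nn.ReLU(),
        )
        self.out_channels = out_channels

    def attention(self, x_low: Tensor, x_high: Tensor) -> Tensor:
        """The gated skip ``x_out = sigmoid(v_h) * (v_o * x_low)`` alone."""
        y_l = self.se(x_low)
        v_h = gem_pool(self.match(x_high).relu(), self.pk)
        n, c = v_h.shape
        return y_l * v_h.sigmoid().reshape(n, c, 1, 1)

    def forward(self, x_low: Tensor, x_high: Tensor) -> Tensor:
        if (x_low.shape[2], x_low.shape[3]) != (2 * x_high.shape[2], 2 * x_high.shape[3]):
            raise ValueError(
                f"skip resolution {x_low.shape[2:]} is not 2x the high-level "
                f"resolution {x_high.shape[2:]}"
            )
        x_out = self.attention(x_low, x_high)
        if self.upsample_mode == "deconv":
            up = self.up(x_high)
        else:
            up = F.interpolate_bilinear(self.up(x_high),
                                        (x_low.shape[2], x_low.shape[3]))
        return self.fuse(concat([x_out, up], axis=1))


class DAC(nn.Module):
    """Dense atrous convolution: parallel dilated 3x3 branches + residual path.

    All-zero branch weights reduce the module to the identity.  Padding equals
    dilation, so spatial size is always preserved.
    """

    def __init__(self, channels: int, dilations: tuple[int, ...] = (1, 3, 5),
                 *, rng: np.random.Generator):
        super().__init__()
        self.dilations = tuple(dilations)
        for i, d in enumerate(self.dilations):
            setattr(self, f"branch{i}",
                    nn.Conv2d(channels, channels, 3, padding=d, dilation=d, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        out = x
        for i in range(len(self.dilations)):
            out = out + getattr(self, f"branch{i}")(x).relu()
        return out


class RMP(nn.Module):
    """Residual multi-kernel pooling: per-size max-pool -> 1x1 conv to one
    channel -> bilinear upsample, concatenated onto the input (+1 channel per
    pool size)."""

    def __init__(self, channels: int, pool_sizes: tuple[int, ...] = (2, 3, 5, 6),
                 *, rng: np.random.Generator):
        super().__init__()
        self.pool_sizes = tuple(pool_sizes)
        self.out_channels = channels + len(self.pool_sizes)
        for i, _ in enumerate(self.pool_sizes):
            setattr(self, f"reduce{i}", nn.Conv2d(channels, 1, 1, rng=rng))

    def forward(self, x: Tensor) -> Tensor:
        h, w = x.shape[2], x.shape[3]
        outs = [x]
        for i, k in enumerate(self.pool_sizes):
            pooled = F.max_pool2d(x, k, stride=k) if k > 1 else x
            reduced = getattr(self, f"reduce{i}")(pooled)
            outs.append(F.interpolate_bilinear(reduced, (h, w)))
        return concat(outs, axis=1)
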