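"""Loss functions and the overlap-error evaluation metric.

The training objective blends pixelwise binary cross-entropy with the
complement of a smoothed dice coefficient,

    L = alpha * CE + (1 - alpha) * (1 - DC_S),

where ``DC_S = (2 sum(p t) + S) / (sum(p) + sum(t) + S)`` and the add-one
smoothing constant ``S`` (default 1) guards the empty-mask 0/0 case.  The
blend weight ``alpha`` trades the two terms; alpha=1 is pure cross-entropy,
alpha=0 the pure dice complement.

Evaluation uses the overlapping error ``E = 1 - |X n Y| / |X u Y|``
(one minus intersection-over-union); lower is better, 0 means identical
masks.
"""

from __future__ import annotations

import numpy as np

from .grad import Tensor

__all__ = [
    "cross_entropy",
    "dice_coefficient",
    "combined_loss",
    "overlapping_error",
    "confusion_counts",
]


def _pair(pred, truth) -> tuple[Tensor, np.ndarray]:
    pred = pred if isinstance(pred, Tensor) else Tensor(pred)
    truth = truth.data if isinstance(truth, Tensor) else np.asarray(truth, dtype=np.float32)
    if pred.shape != truth.shape:
        raise ValueError(f"prediction {pred.shape} and truth {truth.shape} differ")
    if not np.all((truth == 0) | (truth == 1)):
        raise ValueError("ground-truth mask must be strictly binary")
    return pred, truth.astype(np.float32)


def _image_axes(ndim: int) -> tuple[int, ...] | None:
    """Axes spanning one image; arrays of ndim >= 3 carry a leading batch axis."""
    return tuple(range(1, ndim)) if ndim >= 3 else None


def cross_entropy(pred, truth, clip_eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy ``-(t log p + (1-t) log(1-p))`` over pixels.

    Predictions are clamped to ``[clip_eps, 1-clip_eps]`` before the logs, so
    the result is finite for saturated outputs.
    """
    p, t = _pair(pred, truth)
    p = p.clip(clip_eps, 1.0 - clip_eps)
    tt = Tensor(t)
    ll = tt * p.log() + (1.0 - tt) * (1.0 - p).log()
    return -ll.mean()


def dice_coefficient(pred, truth, smooth: float = 0.0) -> Tensor:
    """(Optionally smoothed) dice overlap ``(2 sum(pt) + S)/(sum p + sum t + S)``.

    Computed per image and averaged over the batch when a batch axis is
    present.  ``smooth = 0`` is the raw dice coefficient.
    """
    p, t = _pair(pred, truth)
    tt = Tensor(t)
    axes = _image_axes(p.ndim)
    inter = (p * tt).sum(axis=axes)
    total = p.sum(axis=axes) + tt.sum(axis=axes)
    dice = (2.0 * inter + smooth) / (total + smooth)
    return dice.mean() if axes is not None else dice


def combined_loss(pred, truth, alpha: float = 0.5, smooth: float = 1.0,
                  clip_eps: float = 1e-7) -> Tensor:
    """Convex blend ``alpha * CE + (1 - alpha) * (1 - smoothed dice)``."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0,1]")
    ce = cross_entropy(pred, truth, clip_eps)
    dc = dice_coefficient(pred, truth, smooth)
    return alpha * ce + (1.0 - alpha) * (1.0 - dc)


def confusion_counts(pred_mask, truth_mask) -> tuple[int, int, int]:
    """(TP, FP, FN) pixel counts of two binary masks on a common grid."""
    x = np.asarray(pred_mask)
    y = np.asarray(truth_mask)
    if x.shape != y.shape:
        raise ValueError(f"mask shapes differ: {x.shape} vs {y.shape}")
    for m in (x, y):
        if not np.all((m == 0) | (m == 1)):
            raise ValueError("masks must be strictly binary")
    x = x.astype(bool)
    y = y.astype(bool)
    tp = int(np.count_nonzero(x & y))
    fp = int(np.count_nonzero(x & ~y))
    fn = int(np.count_nonzero(~x & y))
    return tp, fp, fn


def overlapping_error(pred_mask, truth_mask) -> float:
    """Overlap error ``E = 1 - |X n Y|/|X u Y| = (FP+FN)/(TP+FP+FN)``.

    Two empty masks overlap perfectly by convention (E = 0).
    """
    tp, fp, fn = confusion_counts(pred_mask, truth_mask)
    union = tp + fp + fn
    if union == 0:
        return 0.0
    return (fp + fn) / union
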