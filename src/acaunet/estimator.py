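"""Scikit-learn style estimator wrapping the full train/predict pipeline.

:class:`ACAUNetSegmenter` follows the sklearn estimator contract — all
constructor arguments are hyper-parameters stored verbatim, fitted state
lives in trailing-underscore attributes, and ``get_params``/``set_params``
come from :class:`sklearn.base.BaseEstimator` — so it composes with
``clone``, pipelines and grid search.  ``score`` returns mean
intersection-over-union (``1 - E``), so "greater is better" as sklearn
expects.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .config import BlockConfig, NetworkConfig, TrainConfig
from .grad import Tensor, no_grad
from .losses import overlapping_error
from .network import build_network, predict_mask
from .synthetic import SamplePair
from .train import train

__all__ = ["ACAUNetSegmenter"]


class ACAUNetSegmenter(BaseEstimator):
    """Optic-disc segmenter: dense encoder, channel-attention decoder.

    Parameters
    ----------
    growth_rate, layers_per_block, se_reduction, decoder_widths, norm
        Encoder/decoder geometry; the default is the reduced profile that
        trains on a CPU in seconds.
    pk
        GeM pooling exponent of the decoder attention gates (>= 1;
        1 = average pooling, large values approach max pooling).
    alpha, smooth
        Loss blend ``alpha * CE + (1-alpha) * (1 - dice)`` and the dice
        smoothing constant S.
    base_lr, epochs, max_iter, batch_size, poly_power
        Adam/poly-decay training protocol.
    threshold
        Probability cut for hard masks (ties go to foreground).
    seed
        Controls initialisation and data order; fits are reproducible.

    Attributes
    ----------
    network_ : the trained network module
    history_ : per-iteration DataFrame (iter, epoch, lr, loss)
    n_iter_ : number of optimizer steps performed
    """

    def __init__(self, *, growth_rate: int = 8,
                 layers_per_block: tuple[int, ...] = (2, 2, 2, 2),
                 se_reduction: int = 2,
                 decoder_widths: tuple[int, ...] = (32, 16, 8, 8),
                 rmp_pool_sizes: tuple[int, ...] = (1, 2),
                 dac_dilations: tuple[int, ...] = (1, 3, 5),
                 norm: str = "instance",
                 upsample: str = "deconv",
                 pk: float = 5.0,
                 alpha: float = 0.5,
                 smooth: float = 1.0,
                 base_lr: float = 0.03,
                 epochs: int = 25,
                 max_iter: int | None = None,
                 batch_size: int = 1,
                 poly_power: float = 0.9,
                 threshold: float = 0.5,
                 seed: int = 0):
        self.growth_rate = growth_rate
        self.layers_per_block = layers_per_block
        self.se_reduction = se_reduction
        self.decoder_widths = decoder_widths
        self.rmp_pool_sizes = rmp_pool_sizes
        self.dac_dilations = dac_dilations
        self.norm = norm
        self.upsample = upsample
        self.pk = pk
        self.alpha = alpha
        self.smooth = smooth
        self.base_lr = base_lr
        self.epochs = epochs
        self.max_iter = max_iter
        self.batch_size = batch_size
        self.poly_power = poly_power
        self.threshold = threshold
        self.seed = seed

    # ------------------------------------------------------------------ config
    def _network_config(self, input_size: int) -> NetworkConfig:
        return NetworkConfig(
            input_size=input_size,
            decoder_widths=tuple(self.decoder_widths),
            upsample=self.upsample,
            blocks=BlockConfig(
                growth_rate=self.growth_rate,
                layers_per_block=tuple(self.layers_per_block),
                se_reduction=self.se_reduction,
                pk=self.pk,
                dac_dilations=tuple(self.dac_dilations),
                rmp_pool_sizes=tuple(self.rmp_pool_sizes),
                norm=self.norm,
            ),
        )

    def _train_config(self) -> TrainConfig:
        return TrainConfig(
            base_lr=self.base_lr, poly_power=self.poly_power,
            batch_size=self.batch_size, epochs=self.epochs,
            max_iter=self.max_iter, alpha=self.alpha, smooth=self.smooth,
            pk=self.pk, seed=self.seed, val_fraction=0.0,
            threshold=self.threshold,
        )

    @staticmethod
    def _as_images(X) -> np.ndarray:
        """Accept (N,H,W,3) channel-last or (N,3,H,W) channel-first arrays."""
        X = np.asarray(X, dtype=np.float32)
        if X.ndim != 4:
            raise ValueError(f"expected a 4-axis image array, got shape {X.shape}")
        if X.shape[-1] == 3 and X.shape[1] != 3:
            X = X.transpose(0, 3, 1, 2)
        if X.shape[1] != 3:
            raise ValueError("images must have 3 channels")
        return X

    # --------------------------------------------------------------- estimator
    def fit(self, X, y) -> "ACAUNetSegmenter":
        """Train on images ``X`` and binary masks ``y`` (N,H,W)."""
        X = self._as_images(X)
        y = np.asarray(y)
        if y.shape != (X.shape[0], X.shape[2], X.shape[3]):
            raise ValueError(f"mask array {y.shape} does not match images {X.shape}")
        pairs = [
            SamplePair(image=np.ascontiguousarray(img.transpose(1, 2, 0)),
                       mask=m.astype(np.uint8), id=f"fit-{i:04d}")
            for i, (img, m) in enumerate(zip(X, y))
        ]
        cfg = self._network_config(X.shape[2])
        self.network_ = build_network(cfg, seed=self.seed)
        self.history_ = train(self.network_, pairs, self._train_config())
        self.n_iter_ = len(self.history_)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Per-pixel disc probabilities, shape (N,H,W)."""
        if not hasattr(self, "network_"):
            raise RuntimeError("this ACAUNetSegmenter instance is not fitted yet")
        X = self._as_images(X)
        self.network_.eval()
        out = []
        with no_grad():
            for i in range(X.shape[0]):  # one at a time: bounded memory
                p = self.network_(Tensor(X[i : i + 1]))
                out.append(p.data[0, 0])
        return np.stack(out)

    def predict(self, X) -> np.ndarray:
        """Hard binary masks, shape (N,H,W), dtype uint8."""
        return predict_mask(self.predict_proba(X), self.threshold)

    def score(self, X, y) -> float:
        """Mean intersection-over-union (1 - overlap error); higher is better."""
        masks = self.predict(X)
        y = np.asarray(y).astype(np.uint8)
        errs = [overlapping_error(m, t) for m, t in zip(masks, y)]
        return 1.0 - float(np.mean(errs))
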