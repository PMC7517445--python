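"""Training loop, poly learning-rate schedule, evaluation and grid sweep.

The protocol mirrors the usual fully-supervised segmentation recipe: Adam
(default moments), base learning rate 2e-4 decayed per optimizer step by
``(1 - iter/max_iter)^0.9``, batch size 1, the compound dice/cross-entropy
loss, and overlap error E as the evaluation criterion.  Runs are
reproducible bit-for-bit given the seed: all randomness flows through one
``numpy.random.Generator`` and the backend is single-threaded numpy.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .config import NetworkConfig, TrainConfig
from .grad import Tensor, no_grad, optim
from .losses import (combined_loss, confusion_counts, cross_entropy,
                     dice_coefficient, overlapping_error)
from .network import ACAUNet, build_network, predict_mask
from .synthetic import SamplePair, to_batch

logger = logging.getLogger(__name__)

__all__ = ["poly_lr", "train", "evaluate", "sweep"]


def poly_lr(iteration: int, cfg: TrainConfig, max_iter: int | None = None) -> float:
    """Poly schedule ``base_lr * (1 - iter/max_iter)^power``.

    Monotonically non-increasing; equals ``base_lr`` at iteration 0 and 0 at
    ``max_iter``.  Iterations beyond ``max_iter`` clamp to 0 with a warning.
    """
    m = max_iter if max_iter is not None else cfg.max_iter
    if m is None or m < 1:
        raise ValueError("max_iter must be set and positive")
    if iteration < 0:
        raise ValueError("iteration must be non-negative")
    if iteration > m:
        logger.warning("iteration %d beyond max_iter %d; lr clamped to 0", iteration, m)
        return 0.0
    return cfg.base_lr * (1.0 - iteration / m) ** cfg.poly_power


def _split(pairs: list[SamplePair], val_fraction: float,
           rng: np.random.Generator) -> tuple[list[SamplePair], list[SamplePair]]:
    n_val = int(round(val_fraction * len(pairs)))
    if n_val == 0:
        return list(pairs), []
    order = rng.permutation(len(pairs))
    val_idx = set(order[:n_val].tolist())
    train = [p for i, p in enumerate(pairs) if i not in val_idx]
    val = [p for i, p in enumerate(pairs) if i in val_idx]
    return train, val


def train(net: ACAUNet, pairs: list[SamplePair], cfg: TrainConfig,
          out_dir: str | Path | None = None) -> pd.DataFrame:
    """Train ``net`` in place; returns the per-iteration history.

    History columns: iter, epoch, lr, loss, plus ``val_E`` on epoch-final
    rows when a validation split exists.  Aborts on a non-finite loss with
    the offending iteration named.
    """
    if not pairs:
        raise ValueError("training dataset is empty")
    rng = np.random.default_rng(cfg.seed)
    train_pairs, val_pairs = _split(pairs, cfg.val_fraction, rng)
    batches_per_epoch = math.ceil(len(train_pairs) / cfg.batch_size)
    max_iter = cfg.max_iter or cfg.epochs * batches_per_epoch

    opt = optim.Adam(net.parameters(), lr=cfg.base_lr)
    net.train()
    records: list[dict] = []
    it = 0
    for epoch in range(cfg.epochs):
        if it >= max_iter:
            break
        order = rng.permutation(len(train_pairs))
        for b in range(batches_per_epoch):
            if it >= max_iter:
                break
            idx = order[b * cfg.batch_size : (b + 1) * cfg.batch_size]
            batch = [train_pairs[i] for i in idx]
            images, masks = to_batch(batch)
            probs = net(Tensor(images))
            loss = combined_loss(probs, masks[:, None, :, :], cfg.alpha,
                                 cfg.smooth, cfg.clip_eps)
            loss_val = float(loss.data)
            if not np.isfinite(loss_val):
                raise RuntimeError(f"non-finite loss at iteration {it}")
            lr = poly_lr(it, cfg, max_iter)
            opt.zero_grad()
            loss.backward()
            opt.lr = lr
            opt.step()
            records.append({"iter": it, "epoch": epoch, "lr": lr, "loss": loss_val})
            it += 1
        if val_pairs:
            table, summary = evaluate(net, val_pairs, threshold=cfg.threshold)
            records[-1]["val_E"] = summary["mean_E"]
    history = pd.DataFrame.from_records(records)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        net.save(out_dir / "checkpoint.npz")
        history.to_csv(out_dir / "history.csv", index=False)
        _write_manifest(out_dir, net.config, cfg, max_iter)
    return history


def _write_manifest(out_dir: Path, net_cfg: NetworkConfig, cfg: TrainConfig,
                    max_iter: int) -> None:
    import dataclasses
    import hashlib

    cfg_doc = {
        "network": dataclasses.asdict(net_cfg),
        "train": dataclasses.asdict(cfg),
        "max_iter": max_iter,
    }
    blob = json.dumps(cfg_doc, sort_keys=True, default=str)
    manifest = {
        "config": cfg_doc,
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": cfg.seed,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
    }
    try:
        import subprocess

        rev = subprocess.run(["git", "rev-parse", "HEAD"], capture_output=True,
                             text=True, cwd=out_dir, timeout=5)
        manifest["git_revision"] = rev.stdout.strip() or None
    except Exception:
        manifest["git_revision"] = None
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def evaluate(predictor, pairs: list[SamplePair], threshold: float = 0.5,
             csv_path: str | Path | None = None) -> tuple[pd.DataFrame, dict]:
    """Per-image overlap error E, dice and cross-entropy for a predictor.

    ``predictor`` is either a network module or any callable mapping a
    (1,3,H,W) array to a (1,1,H,W) probability map.  Returns the per-image
    table and a summary with mean and median E; ``pooled_E`` aggregates the
    confusion counts over all pixels of all images instead of averaging
    per-image errors.
    """
    if not pairs:
        raise ValueError("evaluation dataset is empty")
    is_module = isinstance(predictor, ACAUNet) or hasattr(predictor, "eval")
    if is_module:
        was_training = getattr(predictor, "training", False)
        predictor.eval()
    rows = []
    pooled = np.zeros(3, dtype=np.int64)  # TP, FP, FN over all pixels
    try:
        for pair in pairs:
            images, masks = to_batch([pair])
            with no_grad():
                probs = predictor(Tensor(images)) if is_module else predictor(images)
            p = probs.data if isinstance(probs, Tensor) else np.asarray(probs)
            p = p.reshape(masks.shape)
            hard = predict_mask(p, threshold)
            pooled += confusion_counts(hard[0], masks[0].astype(np.uint8))
            rows.append({
                "image_id": pair.id,
                "E": overlapping_error(hard[0], masks[0].astype(np.uint8)),
                "DC": float(dice_coefficient(hard[0].astype(np.float32), masks[0]).data),
                "CE": float(cross_entropy(p[0], masks[0]).data),
            })
    finally:
        if is_module and was_training:
            predictor.train()
    table = pd.DataFrame.from_records(rows)
    tp, fp, fn = pooled
    summary = {
        "mean_E": float(table["E"].mean()),
        "median_E": float(table["E"].median()),
        "pooled_E": float((fp + fn) / max(tp + fp + fn, 1)),
    }
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table, summary


def sweep(pairs: list[SamplePair], net_config: NetworkConfig, cfg: TrainConfig,
          pks: list[float], alphas: list[float],
          csv_path: str | Path | None = None) -> pd.DataFrame:
    """Grid sweep over the GeM exponent and the loss blend weight.

    Each cell trains a freshly built network (same seed) and evaluates the
    mean overlap error on the training pairs.
    """
    import dataclasses

    rows = []
    for pk in pks:
        blocks = dataclasses.replace(net_config.blocks, pk=float(pk))
        net_cfg = dataclasses.replace(net_config, blocks=blocks)
        for alpha in alphas:
            run_cfg = dataclasses.replace(cfg, alpha=float(alpha), pk=float(pk))
            net = build_network(net_cfg, seed=run_cfg.seed)
            history = train(net, pairs, run_cfg)
            _, summary = evaluate(net, pairs, threshold=run_cfg.threshold)
            rows.append({
                "pk": float(pk),
                "alpha": float(alpha),
                "mean_E": summary["mean_E"],
                "final_loss": float(history["loss"].iloc[-1]),
            })
    table = pd.DataFrame.from_records(rows)
    if csv_path is not None:
        table.to_csv(csv_path, index=False)
    return table
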