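"""Supervised training loop: Adam on binary cross-entropy with early stopping.

The recipe is fixed to the study conditions: batch size 128, Adam with
learning rate 0.01 and weight decay 1e-4, at most 200 epochs with early
stopping after 10 epochs without improvement of the monitored loss. The
monitored loss is the binary cross-entropy on a held-out validation split
(default 10%, stratified by label) — the most common reading of an
unqualified early-stopping rule.

An optional cleaning hook runs on a fixed epoch schedule and may only shrink
the set of actively trained samples (monotone pruning); removals are
permanent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .network import Classifier, _BatchNorm1d, _Dropout, _sigmoid
from .synthetic import EcgSegment

__all__ = ["TrainConfig", "LabeledDataset", "TrainingError", "train",
           "evaluate_loss", "bce_loss"]

_EPS = 1e-7  # probability clamp before taking logs


class TrainingError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    batch_size: int = 128
    learning_rate: float = 0.01
    weight_decay: float = 0.0001
    max_epochs: int = 200
    patience: int = 10
    val_fraction: float = 0.1
    monitor: str = "val"  # loss driving early stopping: "val" or "train"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.patience < 1 or self.batch_size < 1:
            raise ValueError("patience and batch_size must be >= 1")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must lie in (0, 1)")
        if self.monitor not in ("val", "train"):
            raise ValueError("monitor must be 'val' or 'train'")


@dataclass
class LabeledDataset:
    """Signals with binary labels (0 = sinus, 1 = AF) and an activity mask."""

    signals: np.ndarray  # (N, leads, samples) float32
    labels: np.ndarray   # (N,) in {0, 1}
    active_mask: np.ndarray | None = None
    segments: list[EcgSegment] | None = None
    val_mask: np.ndarray | None = None  # set by train(): held-out split

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=np.float32)
        self.labels = np.asarray(self.labels).astype(np.int64)
        n = len(self.labels)
        if self.signals.shape[0] != n:
            raise ValueError("labels length must equal segment count")
        if self.active_mask is None:
            self.active_mask = np.ones(n, dtype=bool)
        self.active_mask = np.asarray(self.active_mask, dtype=bool)
        if self.active_mask.shape[0] != n:
            raise ValueError("active_mask length must equal segment count")

    @classmethod
    def from_segments(cls, segments: Sequence[EcgSegment],
                      labels: np.ndarray | None = None) -> "LabeledDataset":
        sigs = np.stack([s.signal for s in segments])
        if labels is None:
            labels = np.array([s.label for s in segments])
        return cls(signals=sigs, labels=np.asarray(labels), segments=list(segments))

    def __len__(self) -> int:
        return len(self.labels)


def bce_loss(p: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy with probabilities clamped to [1e-7, 1-1e-7]."""
    p = np.clip(np.asarray(p, dtype=np.float64), _EPS, 1.0 - _EPS)
    y = np.asarray(y, dtype=np.float64)
    return float(-np.mean(y * np.log(p) + (1.0 - y) * np.log1p(-p)))


def evaluate_loss(model: Classifier, data: LabeledDataset,
                  batch_size: int = 256, bn_stats: str | None = None) -> float:
    """Mean BCE over the active samples of ``data`` (deterministic passes)."""
    idx = np.flatnonzero(data.active_mask)
    if idx.size == 0:
        raise TrainingError("no active samples to evaluate")
    probs = predict_proba_batched(model, data.signals[idx], batch_size, bn_stats)
    return bce_loss(probs, data.labels[idx])


def predict_proba_batched(model: Classifier, signals: np.ndarray,
                          batch_size: int = 256,
                          bn_stats: str | None = None) -> np.ndarray:
    out = np.empty(signals.shape[0], dtype=np.float64)
    for lo in range(0, signals.shape[0], batch_size):
        out[lo:lo + batch_size] = model.predict_proba(
            signals[lo:lo + batch_size], bn_stats=bn_stats)
    return out


def refresh_batchnorm_stats(model: Classifier, signals: np.ndarray,
                            batch_size: int = 512,
                            which: tuple = ("det", "mc"),
                            seed: int = 0) -> None:
    """Re-estimate batch-norm running statistics with the final weights.

    Two mismatches build up during training. First, the statistics are
    accumulated from dropout-noised activations, so deterministic inference
    sees systematically smaller activation variance than the stored
    statistics assume, which damps the logits: the "det" pass re-estimates
    a dropout-off statistics set. Second, the training-accumulated set
    itself reflects batches computed under *changing* weights; the "mc"
    pass re-estimates it under the final weights with dropout active (a
    seeded mask stream), which markedly stabilizes Monte Carlo dropout
    predictions. Each pass is one gradient-free sweep over the training
    signals accumulating exact pooled per-channel statistics (batches are
    normalized by their own batch statistics while sweeping, as in
    training).
    """

    def _sweep(stat_prefix: str, dropout_on: bool,
               rng: np.random.Generator | None) -> None:
        acc = {}  # bn layer -> [weight_sum, mean_sum, second_moment_sum]
        for lo in range(0, signals.shape[0], batch_size):
            x = np.asarray(signals[lo:lo + batch_size], dtype=np.float32)
            x = np.ascontiguousarray(x.transpose(1, 0, 2))
            w = x.shape[1]
            for block in model.blocks:
                for layer in block:
                    if isinstance(layer, _Dropout):
                        x = layer.forward(x, False, active=dropout_on, rng=rng)
                    elif isinstance(layer, _BatchNorm1d):
                        mean = x.mean(axis=(1, 2))
                        var = x.var(axis=(1, 2))
                        tot = acc.setdefault(id(layer), [0.0, 0.0, 0.0, layer])
                        tot[0] += w
                        tot[1] += w * mean
                        tot[2] += w * (var + mean * mean)
                        inv = (1.0 / np.sqrt(var + layer.eps)).astype(x.dtype)
                        x = (x - mean[:, None, None]) * inv[:, None, None]
                        x = (layer.gamma[:, None, None] * x
                             + layer.beta[:, None, None])
                    else:
                        x = layer.forward(x, False)
        for wsum, msum, ssum, layer in acc.values():
            pooled_mean = msum / wsum
            pooled_var = ssum / wsum - pooled_mean * pooled_mean
            getattr(layer, f"{stat_prefix}_mean")[...] = pooled_mean
            getattr(layer, f"{stat_prefix}_var")[...] = np.maximum(pooled_var, 0.0)

    if "det" in which:
        _sweep("det", False, None)
    if "mc" in which and model.config.dropout_rate > 0:
        _sweep("run", True, np.random.Generator(np.random.SFC64(seed)))
    else:
        # without stochastic units the two inference modes coincide
        for block in model.blocks:
            for layer in block:
                if isinstance(layer, _BatchNorm1d) and "det" in which:
                    layer.run_mean[...] = layer.det_mean
                    layer.run_var[...] = layer.det_var


class _Adam:
    def __init__(self, params, lr: float, weight_decay: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)  # (param, grad, decay) triples
        self.lr, self.wd = lr, weight_decay
        self.b1, self.b2, self.eps = betas[0], betas[1], eps
        self.t = 0
        self.m = [np.zeros_like(p) for p, _, _ in self.params]
        self.v = [np.zeros_like(p) for p, _, _ in self.params]

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, (p, g, decay) in enumerate(self.params):
            grad = g.astype(np.float64)
            if decay and self.wd:
                grad = grad + self.wd * p
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * grad
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * grad * grad
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(p.dtype)


def _stratified_val_split(rng: np.random.Generator, labels: np.ndarray,
                          idx: np.ndarray, val_fraction: float
                          ) -> tuple[np.ndarray, np.ndarray]:
    val_parts = []
    for cls in (0, 1):
        cls_idx = idx[labels[idx] == cls]
        perm = rng.permutation(cls_idx)
        n_val = max(1, int(round(val_fraction * cls_idx.size))) if cls_idx.size > 1 else 0
        val_parts.append(perm[:n_val])
    val_idx = np.sort(np.concatenate(val_parts))
    train_idx = np.setdiff1d(idx, val_idx)
    return train_idx, val_idx


def train(
    model: Classifier,
    data: LabeledDataset,
    config: TrainConfig | None = None,
    cleaner: Callable | None = None,
) -> tuple[Classifier, pd.DataFrame]:
    """Train ``model`` in place; returns it with a per-epoch history table.

    ``cleaner`` is an optional hook ``(model, data, candidate_idx, epoch) ->
    indices to deactivate``; it is the only mechanism allowed to change
    ``data.active_mask`` and may only shrink it. History columns: epoch,
    train_loss, val_loss, active_count.
    """
    config = config or TrainConfig()
    # SFC64: dropout-mask generation is on the hot path
    rng = np.random.Generator(np.random.SFC64(config.seed))
    active = np.flatnonzero(data.active_mask)
    if np.unique(data.labels[active]).size < 2:
        raise TrainingError("training requires active samples of both classes")
    train_idx, val_idx = _stratified_val_split(rng, data.labels, active,
                                               config.val_fraction)
    data.val_mask = np.zeros(len(data), dtype=bool)
    data.val_mask[val_idx] = True
    if np.unique(data.labels[train_idx]).size < 2:
        raise TrainingError("training split lost a class; decrease val_fraction")

    opt = _Adam(model.parameters(), config.learning_rate, config.weight_decay)
    best_val = np.inf
    best_state: list[np.ndarray] | None = None
    epochs_since_best = 0
    history = []
    for epoch in range(1, config.max_epochs + 1):
        cur = train_idx[data.active_mask[train_idx]]
        order = rng.permutation(cur)
        losses = []
        for lo in range(0, order.size, config.batch_size):
            batch = order[lo:lo + config.batch_size]
            x = data.signals[batch]
            y = data.labels[batch].astype(np.float64)
            z = model.forward(x, train=True, dropout_active=True, rng=rng)
            p = _sigmoid(z)
            # numerically stable BCE-with-logits
            loss = np.mean(np.maximum(z, 0) - z * y + np.log1p(np.exp(-np.abs(z))))
            model.backward(((p - y) / y.size).astype(np.float32))
            opt.step()
            losses.append(float(loss))
        val_subset = LabeledDataset(data.signals[val_idx], data.labels[val_idx])
        # mid-training evaluation uses the training-accumulated statistics;
        # the deterministic set is only re-estimated after training
        val_loss = evaluate_loss(model, val_subset, bn_stats="mc")
        history.append(
            {"epoch": epoch, "train_loss": float(np.mean(losses)),
             "val_loss": val_loss, "active_count": int(data.active_mask.sum())}
        )
        monitored = val_loss if config.monitor == "val" else float(np.mean(losses))
        if monitored < best_val:
            best_val = monitored
            best_state = _snapshot(model)
            epochs_since_best = 0
        else:
            epochs_since_best += 1
        if cleaner is not None:
            candidates = train_idx[data.active_mask[train_idx]]
            remove = np.asarray(cleaner(model, data, candidates, epoch), dtype=int)
            if remove.size:
                if not np.isin(remove, candidates).all():
                    raise TrainingError("cleaner returned non-candidate indices")
                data.active_mask[remove] = False
                history[-1]["active_count"] = int(data.active_mask.sum())
        if epochs_since_best >= config.patience:
            break
    if best_state is not None:
        _restore(model, best_state)
    refresh_batchnorm_stats(model,
                            data.signals[train_idx[data.active_mask[train_idx]]],
                            seed=config.seed)
    return model, pd.DataFrame(history)


_STAT_NAMES = ("run_mean", "run_var", "det_mean", "det_var")


def _snapshot(model: Classifier) -> list[np.ndarray]:
    state = [p.copy() for p, _, _ in model.parameters()]
    for layer in model._layers():
        for name in _STAT_NAMES:
            if hasattr(layer, name):
                state.append(getattr(layer, name).copy())
    return state


def _restore(model: Classifier, state: list[np.ndarray]) -> None:
    it = iter(state)
    for p, _, _ in model.parameters():
        p[...] = next(it)
    for layer in model._layers():
        for name in _STAT_NAMES:
            if hasattr(layer, name):
                getattr(layer, name)[...] = next(it)
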