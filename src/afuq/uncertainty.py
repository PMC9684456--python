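"""Predictive uncertainty: Monte Carlo dropout, test-time augmentation, both.

Three sampling modes are built on the same classifier:

* epistemic — T stochastic forward passes with dropout kept active at
  inference (Monte Carlo dropout) on the unaugmented input;
* aleatoric — T deterministic passes on independently augmented views of the
  input, where the augmentation is 10% random masking (zeroing) of time
  points, shared across leads;
* combined — T passes each with dropout active and an independent masked
  view (joint sampling).

The aggregate prediction is the mean of the T sampled probabilities and the
uncertainty estimate is their sample standard deviation. Mode ``none`` is
the always-confident baseline: a single deterministic pass with the
uncertainty defined as zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import Classifier
from .synthetic import EcgSegment

__all__ = [
    "UncertaintyConfig", "PredictiveDistribution", "PredictionSet",
    "mask_augment", "predict_with_uncertainty", "batch_uncertainty",
]

MODES = ("none", "epistemic", "aleatoric", "combined")


@dataclass(frozen=True)
class UncertaintyConfig:
    mode: str = "combined"
    n_passes: int = 30
    mask_fraction: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode != "none" and self.n_passes < 2:
            raise ValueError("n_passes must be >= 2 for any sampling mode")
        if not 0.0 <= self.mask_fraction < 1.0:
            raise ValueError("mask_fraction must lie in [0, 1)")


@dataclass
class PredictiveDistribution:
    """Sampled probabilities for one input with mean and std summaries."""

    samples: np.ndarray  # (T,) sampled p(AF)
    mean: float
    std: float

    @classmethod
    def from_samples(cls, samples: np.ndarray) -> "PredictiveDistribution":
        samples = np.asarray(samples, dtype=np.float64)
        std = float(samples.std(ddof=1)) if samples.size > 1 else 0.0
        return cls(samples=samples, mean=float(samples.mean()), std=std)


@dataclass
class PredictionSet:
    """Per-segment predictions with ground truth and grouping flags."""

    mean: np.ndarray         # aggregate p(AF)
    std: np.ndarray          # uncertainty estimate
    labels: np.ndarray       # binary label; -1 for OOD segments
    noisy: np.ndarray        # bool flags
    ood: np.ndarray          # bool flags
    mode: str = "none"
    n_passes: int = 1

    def id_mask(self) -> np.ndarray:
        return ~self.ood


def mask_augment(signal: np.ndarray, fraction: float,
                 seed: int | np.random.Generator = 0) -> np.ndarray:
    """Zero exactly round(fraction * samples) time points across all leads.

    Positions are drawn uniformly without replacement; deterministic given
    ``seed``.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    signal = np.asarray(signal)
    out = signal.copy()
    n = signal.shape[-1]
    n_mask = int(round(fraction * n))
    if n_mask == 0:
        return out
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = rng.choice(n, size=n_mask, replace=False)
    out[..., pos] = 0
    return out


def _sample_probs(model: Classifier, signals: np.ndarray,
                  config: UncertaintyConfig, seed: int) -> np.ndarray:
    """(N, T) sampled probabilities under the configured mode."""
    n = signals.shape[0]
    if config.mode == "none":
        return model.predict_proba(signals)[:, None]
    ss = np.random.SeedSequence(seed)
    drop_rng = np.random.Generator(np.random.SFC64(ss.spawn(1)[0]))
    mask_rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(seed + 1).spawn(n)]
    use_mask = config.mode in ("aleatoric", "combined")
    use_drop = config.mode in ("epistemic", "combined")
    out = np.empty((n, config.n_passes), dtype=np.float64)
    for t in range(config.n_passes):
        if use_mask and config.mask_fraction > 0:
            x = np.stack([
                mask_augment(signals[i], config.mask_fraction, mask_rngs[i])
                for i in range(n)
            ])
        else:
            x = signals
        out[:, t] = model.predict_proba(x, dropout_active=use_drop, rng=drop_rng)
    return out


def predict_with_uncertainty(model: Classifier, segment: EcgSegment | np.ndarray,
                             config: UncertaintyConfig) -> PredictiveDistribution:
    """Sampled predictive distribution for one segment.

    Mode ``none`` performs a single deterministic pass with std defined as 0;
    the sampling modes draw ``n_passes`` probabilities as documented in the
    module docstring. Reproducible given ``config.seed``.
    """
    signal = segment.signal if isinstance(segment, EcgSegment) else np.asarray(segment)
    samples = _sample_probs(model, signal[None], config, config.seed)[0]
    return PredictiveDistribution.from_samples(samples)


def batch_uncertainty(model: Classifier, segments: Sequence[EcgSegment],
                      config: UncertaintyConfig) -> PredictionSet:
    """Sampled predictions for a set of segments (vectorized over the batch).

    Per-segment augmentation streams are seeded independently from the master
    seed; noisy/OOD flags are carried through for downstream grouping. OOD
    segments receive label -1.
    """
    if len(segments) == 0:
        raise ValueError("segments must be non-empty")
    signals = np.stack([s.signal for s in segments])
    samples = _sample_probs(model, signals, config, config.seed)
    std = samples.std(axis=1, ddof=1) if samples.shape[1] > 1 else np.zeros(len(segments))
    labels = np.array([-1 if s.true_rhythm == "ood" else s.label for s in segments])
    return PredictionSet(
        mean=samples.mean(axis=1),
        std=std,
        labels=labels,
        noisy=np.array([s.noisy for s in segments], dtype=bool),
        ood=np.array([s.true_rhythm == "ood" for s in segments], dtype=bool),
        mode=config.mode,
        n_passes=samples.shape[1],
    )
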