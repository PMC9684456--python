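"""Synthetic ECG cohort generation.

Produces 10-s, multi-lead ECG-like segments at 240 Hz with the statistical
structure that separates sinus rhythm from atrial fibrillation (AF) on a
rhythm strip: sinus segments have near-regular RR intervals and a visible
P-wave before each QRS complex; AF segments have highly irregular RR
intervals, no P-wave, and a low-amplitude fibrillatory baseline oscillation.
An out-of-distribution (OOD) generator emulates segments a human reviewer
would abstain on (boundary-region rhythm cues under moderate artifact).

Waveforms are built from a parametric beat template (Gaussian bumps for the
P, Q, R, S and T waves) rather than a dynamical ECG model: downstream
analyses depend only on rhythm statistics and on morphology presence or
absence, not on clinical fidelity. Leads are correlated copies of a single
source waveform with per-lead gain and an independent noise floor.

Every generator is a pure function of its seed and parameters.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EcgSegment",
    "RhythmSpec",
    "NoiseSpec",
    "LabelNoiseModel",
    "DomainShift",
    "sinus_preset",
    "af_preset",
    "generate_segment",
    "generate_ood_segment",
    "inject_noise",
    "generate_cohort",
    "corrupt_labels",
    "save_cohort",
    "load_cohort",
]

DEFAULT_FS = 240.0
DEFAULT_DURATION = 10.0
DEFAULT_LEADS = 4

#: fraction of a record that must be affected by artifact for the segment to
#: be flagged noisy (the annotation criterion: at least 1/4 of the recording)
NOISY_FRACTION_THRESHOLD = 0.25


@dataclass
class EcgSegment:
    """One fixed-duration multi-lead ECG-like waveform with ground truth."""

    signal: np.ndarray  # (leads, samples), millivolt scale, float32
    fs: float = DEFAULT_FS
    duration: float = DEFAULT_DURATION
    patient_id: str = ""
    timestamp: float = 0.0  # seconds since patient admission
    true_rhythm: str = "sinus"  # one of {"sinus", "af", "ood"}
    noisy: bool = False
    dropoff: bool = False

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=np.float32)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a (leads, samples) matrix")
        expected = int(round(self.fs * self.duration))
        if self.signal.shape[1] != expected:
            raise ValueError(
                f"samples ({self.signal.shape[1]}) != round(fs*duration) ({expected})"
            )
        if self.true_rhythm not in ("sinus", "af", "ood"):
            raise ValueError(f"unknown rhythm {self.true_rhythm!r}")
        if not self.dropoff and not np.isfinite(self.signal).all():
            raise ValueError("non-finite signal values on a non-dropoff segment")

    @property
    def n_leads(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def label(self) -> int:
        """Binary training label: 0 = sinus rhythm, 1 = AF. OOD has no label."""
        if self.true_rhythm == "ood":
            raise ValueError("OOD segments carry no binary rhythm label")
        return int(self.true_rhythm == "af")


@dataclass(frozen=True)
class RhythmSpec:
    """Rhythm-level parameters for a generated segment.

    ``rr_cv`` is the coefficient of variation of RR intervals, the quantity
    that separates AF (irregular, cv >= 0.15) from sinus rhythm (regular,
    cv <= 0.05). ``p_wave_amplitude`` is relative to the R-wave (amplitude 1);
    zero disables the P-wave, as in AF. ``fibrillatory_amplitude`` adds the
    irregular 4-9 Hz baseline oscillation characteristic of AF.
    """

    heart_rate_bpm: float = 75.0
    rr_cv: float = 0.02
    p_wave_amplitude: float = 0.15
    fibrillatory_amplitude: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rr_cv < 0:
            raise ValueError("rr_cv must be non-negative")
        if self.p_wave_amplitude < 0 or self.fibrillatory_amplitude < 0:
            raise ValueError("amplitudes must be non-negative")


def sinus_preset(seed: int = 0, heart_rate_bpm: float = 75.0) -> RhythmSpec:
    """Regular rhythm with a P-wave: rr_cv <= 0.05, p_wave_amplitude > 0."""
    return RhythmSpec(
        heart_rate_bpm=heart_rate_bpm,
        rr_cv=0.02,
        p_wave_amplitude=0.15,
        fibrillatory_amplitude=0.0,
        seed=seed,
    )


def af_preset(seed: int = 0, heart_rate_bpm: float = 95.0) -> RhythmSpec:
    """Irregular rhythm without a P-wave: rr_cv >= 0.15, p_wave_amplitude = 0."""
    return RhythmSpec(
        heart_rate_bpm=heart_rate_bpm,
        rr_cv=0.25,
        p_wave_amplitude=0.0,
        fibrillatory_amplitude=0.10,
        seed=seed,
    )


@dataclass(frozen=True)
class NoiseSpec:
    """One artifact to superimpose on a contiguous region of a segment."""

    kind: str = "hf_artifact"  # {"hf_artifact", "baseline_wander", "dropoff"}
    fraction: float = 0.5  # fraction of the record affected
    amplitude: float = 0.5  # relative amplitude (mV scale)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("hf_artifact", "baseline_wander", "dropoff"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        if self.amplitude < 0:
            raise ValueError("amplitude must be non-negative")


@dataclass(frozen=True)
class LabelNoiseModel:
    """Independent label-flip model: flip[a][b] = P(observe b | true a)."""

    flip: tuple = ((1.0, 0.0), (0.0, 1.0))
    seed: int = 0

    def matrix(self) -> np.ndarray:
        m = np.asarray(self.flip, dtype=float)
        if m.shape != (2, 2):
            raise ValueError("flip must be a 2x2 matrix")
        if (m < 0).any() or (m > 1).any():
            raise ValueError("flip entries must lie in [0, 1]")
        if np.abs(m.sum(axis=1) - 1.0).max() > 1e-12:
            raise ValueError("flip rows must each sum to 1 (within 1e-12)")
        return m

    @staticmethod
    def symmetric(rate: float, seed: int = 0) -> "LabelNoiseModel":
        return LabelNoiseModel(
            flip=((1.0 - rate, rate), (rate, 1.0 - rate)), seed=seed
        )


@dataclass(frozen=True)
class DomainShift:
    """Parameter offsets emulating a diagnostic-ECG vs ICU-telemetry gap.

    Applied to a whole cohort: multiplicative amplitude scaling, an additive
    broadband noise floor (mV), and a shift of the heart-rate distribution.
    """

    amplitude_scale: float = 1.0
    noise_floor: float = 0.0
    heart_rate_shift_bpm: float = 0.0


# ---------------------------------------------------------------------------
# waveform synthesis


def _gaussian_bump(t: np.ndarray, center: float, width: float, amp: float,
                   out: np.ndarray) -> None:
    # only evaluate within 4 sigma of the center to keep synthesis cheap
    lo = np.searchsorted(t, center - 4 * width)
    hi = np.searchsorted(t, center + 4 * width)
    if hi > lo:
        out[lo:hi] += amp * np.exp(-0.5 * ((t[lo:hi] - center) / width) ** 2)


def _draw_rr_intervals(rng: np.random.Generator, mean_rr: float, cv: float,
                       total: float) -> np.ndarray:
    """Log-normal RR intervals with the requested mean and CV (positive, skewed)."""
    n_guess = max(4, int(total / mean_rr * 2) + 4)
    if cv <= 0:
        rr = np.full(n_guess, mean_rr)
    else:
        sigma2 = math.log(1.0 + cv * cv)
        mu = math.log(mean_rr) - 0.5 * sigma2
        rr = rng.lognormal(mean=mu, sigma=math.sqrt(sigma2), size=n_guess)
        # physiological refractory floor
        rr = np.maximum(rr, 0.22)
    while rr.sum() < total + mean_rr:
        rr = np.concatenate([rr, rr])
    return rr


def _beat_train(rng: np.random.Generator, t: np.ndarray, spec: RhythmSpec,
                duration: float, qrs_width: float = 0.014) -> np.ndarray:
    mean_rr = 60.0 / spec.heart_rate_bpm
    rr = _draw_rr_intervals(rng, mean_rr, spec.rr_cv, duration)
    beats = np.cumsum(rr) - rr[0] + rng.uniform(0.1, 0.4)
    beats = beats[beats < duration + 0.3]
    base = np.zeros_like(t)
    for b in beats:
        if spec.p_wave_amplitude > 0:
            _gaussian_bump(t, b - 0.16, 0.025, spec.p_wave_amplitude, base)
        _gaussian_bump(t, b - 0.035, 0.012, -0.10, base)       # Q
        _gaussian_bump(t, b, qrs_width, 1.0, base)             # R
        _gaussian_bump(t, b + 0.035, 0.012, -0.15, base)       # S
        _gaussian_bump(t, b + 0.28, 0.055, 0.25, base)         # T
    if spec.fibrillatory_amplitude > 0:
        # irregular atrial (f-wave) oscillation, a few components in 4-9 Hz
        fib = np.zeros_like(t)
        for _ in range(3):
            f = rng.uniform(4.0, 9.0)
            phase = rng.uniform(0, 2 * np.pi)
            fib += np.sin(2 * np.pi * f * t + phase)
        base += spec.fibrillatory_amplitude * fib / 3.0
    return base


def _to_leads(rng: np.random.Generator, base: np.ndarray, leads: int,
              noise_floor: float = 0.01) -> np.ndarray:
    """Correlated lead copies: per-lead gain plus an independent noise floor."""
    gains = np.linspace(1.0, 0.6, leads)
    sig = gains[:, None] * base[None, :]
    sig = sig + rng.normal(0.0, noise_floor, size=sig.shape)
    return sig.astype(np.float32)


def generate_segment(
    spec: RhythmSpec,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
    leads: int = DEFAULT_LEADS,
    *,
    rhythm: str | None = None,
) -> EcgSegment:
    """Generate one segment whose beat times follow ``spec``.

    RR intervals are drawn log-normally with the requested mean (60/heart
    rate) and coefficient of variation; P-wave bumps are present iff
    ``p_wave_amplitude > 0``. Deterministic given ``spec.seed``.

    ``rhythm`` overrides the inferred ground-truth tag (AF iff the P-wave is
    absent and rr_cv >= 0.15).
    """
    if not 20.0 <= spec.heart_rate_bpm <= 250.0:
        raise ValueError("heart_rate_bpm must lie in [20, 250]")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if leads < 1:
        raise ValueError("need at least one lead")
    rng = np.random.default_rng(spec.seed)
    n = int(round(fs * duration))
    t = np.arange(n) / fs
    base = _beat_train(rng, t, spec, duration)
    sig = _to_leads(rng, base, leads)
    if rhythm is None:
        rhythm = "af" if (spec.p_wave_amplitude == 0 and spec.rr_cv >= 0.15) else "sinus"
    return EcgSegment(signal=sig, fs=fs, duration=duration, true_rhythm=rhythm)


def generate_ood_segment(
    seed: int,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
    leads: int = DEFAULT_LEADS,
) -> EcgSegment:
    """Out-of-distribution segment emulating records reviewers abstain on.

    Abstentions are records too unclear to assign to either rhythm class, so
    the generator draws from the boundary region between the classes:
    intermediate RR irregularity (CV 0.06-0.14, between the sinus and AF
    presets), a faint P-wave, slight fibrillatory activity, and a moderate
    artifact covering at least a quarter of the record. Such segments carry
    genuinely conflicting rhythm cues rather than a clean class signature.
    """
    rng = np.random.default_rng(seed)
    spec = RhythmSpec(
        heart_rate_bpm=float(rng.uniform(55.0, 110.0)),
        rr_cv=float(rng.uniform(0.06, 0.14)),
        p_wave_amplitude=float(rng.uniform(0.03, 0.08)),
        fibrillatory_amplitude=float(rng.uniform(0.02, 0.06)),
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    seg = generate_segment(spec, fs, duration, leads, rhythm="ood")
    kind = "hf_artifact" if rng.random() < 0.5 else "baseline_wander"
    amplitude = rng.uniform(0.2, 0.45) if kind == "hf_artifact" else rng.uniform(0.3, 0.6)
    return inject_noise(seg, NoiseSpec(kind=kind,
                                       fraction=float(rng.uniform(0.3, 0.7)),
                                       amplitude=float(amplitude),
                                       seed=int(rng.integers(0, 2**31 - 1))))


# ---------------------------------------------------------------------------
# noise injection


def inject_noise(segment: EcgSegment, spec: NoiseSpec) -> EcgSegment:
    """Superimpose one artifact on a contiguous region of a copy of ``segment``.

    The ``noisy`` flag is set iff the affected fraction reaches 1/4 of the
    record, implementing the annotation criterion exactly. ``dropoff``
    replaces the affected region with a flat run and sets the dropoff flag.
    """
    sig = segment.signal.astype(np.float32).copy()
    n = sig.shape[1]
    rng = np.random.default_rng(spec.seed)
    length = int(round(spec.fraction * n))
    dropoff = segment.dropoff
    if length > 0:
        start = int(rng.integers(0, n - length + 1))
        sl = slice(start, start + length)
        t = np.arange(start, start + length) / segment.fs
        if spec.kind == "hf_artifact":
            sig[:, sl] += rng.normal(0.0, spec.amplitude,
                                     size=(sig.shape[0], length)).astype(np.float32)
        elif spec.kind == "baseline_wander":
            f = rng.uniform(0.15, 0.5)  # low-frequency drift, well below 1 Hz
            phase = rng.uniform(0, 2 * np.pi)
            drift = spec.amplitude * np.sin(2 * np.pi * f * t + phase)
            sig[:, sl] += drift.astype(np.float32)[None, :]
        else:  # dropoff: hold the last pre-gap value (flat run)
            hold = sig[:, start - 1] if start > 0 else np.zeros(sig.shape[0], np.float32)
            sig[:, sl] = hold[:, None]
            dropoff = True
    noisy = segment.noisy or spec.fraction >= NOISY_FRACTION_THRESHOLD
    return dataclasses.replace(segment, signal=sig, noisy=noisy, dropoff=dropoff)


# ---------------------------------------------------------------------------
# cohorts


def _seg_count(spec, rng: np.random.Generator) -> int:
    if callable(spec):
        return int(spec(rng))
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        return int(rng.integers(spec[0], spec[1] + 1))
    return int(spec)


def generate_cohort(
    n_patients: int,
    segments_per_patient: int | tuple | Callable = 5,
    class_mix: dict | None = None,
    noise_rate: float = 0.0,
    ood_rate: float = 0.0,
    dropoff_rate: float = 0.0,
    domain_shift: DomainShift | None = None,
    seed: int = 0,
    *,
    fs: float = DEFAULT_FS,
    duration: float = DEFAULT_DURATION,
    leads: int = DEFAULT_LEADS,
    min_spacing: float = 3600.0,
) -> list[EcgSegment]:
    """Generate a per-patient structured cohort of segments.

    ``class_mix`` gives {"sinus": q, "af": 1-q} proportions over the
    in-distribution segments; each segment is independently OOD with
    probability ``ood_rate``, receives a supra-threshold artifact with
    probability ``noise_rate``, and a sensor drop-off (flat run, flagged)
    with probability ``dropoff_rate``. Per-patient timestamps are spaced at least
    ``min_spacing`` seconds apart. Reproducible given ``seed``.
    """
    if n_patients <= 0:
        raise ValueError("n_patients must be positive")
    class_mix = dict(class_mix or {"sinus": 0.8, "af": 0.2})
    probs = np.array([class_mix.get("sinus", 0.0), class_mix.get("af", 0.0)])
    if abs(probs.sum() - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    for r, name in ((noise_rate, "noise_rate"), (ood_rate, "ood_rate"),
                    (dropoff_rate, "dropoff_rate")):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    shift = domain_shift or DomainShift()
    rng = np.random.default_rng(seed)
    segments: list[EcgSegment] = []
    for p in range(n_patients):
        pid = f"P{p:05d}"
        n_seg = _seg_count(segments_per_patient, rng)
        ts = 0.0
        for _ in range(n_seg):
            ts += min_spacing + rng.exponential(0.5 * min_spacing)
            seg_seed = int(rng.integers(0, 2**31 - 1))
            if rng.random() < ood_rate:
                seg = generate_ood_segment(seg_seed, fs, duration, leads)
            else:
                is_af = rng.random() < probs[1]
                hr_lo, hr_hi = (80.0, 140.0) if is_af else (50.0, 100.0)
                hr = rng.uniform(hr_lo, hr_hi) + shift.heart_rate_shift_bpm
                hr = float(np.clip(hr, 25.0, 245.0))
                if is_af:
                    spec = dataclasses.replace(af_preset(seg_seed), heart_rate_bpm=hr)
                else:
                    spec = dataclasses.replace(sinus_preset(seg_seed), heart_rate_bpm=hr)
                seg = generate_segment(spec, fs, duration, leads)
                if rng.random() < noise_rate:
                    kind = "hf_artifact" if rng.random() < 0.5 else "baseline_wander"
                    amp = rng.uniform(0.3, 0.8) if kind == "hf_artifact" else rng.uniform(0.4, 1.0)
                    nspec = NoiseSpec(kind=kind,
                                      fraction=float(rng.uniform(0.3, 0.9)),
                                      amplitude=float(amp),
                                      seed=int(rng.integers(0, 2**31 - 1)))
                    seg = inject_noise(seg, nspec)
                if rng.random() < dropoff_rate:
                    seg = inject_noise(seg, NoiseSpec(
                        kind="dropoff", fraction=float(rng.uniform(0.05, 0.3)),
                        seed=int(rng.integers(0, 2**31 - 1))))
            sig = seg.signal * np.float32(shift.amplitude_scale)
            if shift.noise_floor > 0:
                sig = sig + rng.normal(0.0, shift.noise_floor, sig.shape).astype(np.float32)
            seg = dataclasses.replace(seg, signal=sig, patient_id=pid, timestamp=ts)
            segments.append(seg)
    return segments


def corrupt_labels(labels: np.ndarray, model: LabelNoiseModel
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Flip each binary label independently per the flip matrix.

    Returns ``(observed_labels, flipped_indices)``; deterministic given
    ``model.seed``.
    """
    labels = np.asarray(labels)
    if not np.isin(labels, (0, 1)).all():
        raise ValueError("labels must be binary")
    m = model.matrix()
    rng = np.random.default_rng(model.seed)
    u = rng.random(labels.shape[0])
    p_flip = np.where(labels == 0, m[0, 1], m[1, 0])
    flipped = u < p_flip
    observed = np.where(flipped, 1 - labels, labels).astype(labels.dtype)
    return observed, np.flatnonzero(flipped)


# ---------------------------------------------------------------------------
# persistence: one npz for the signal stack + one CSV of per-segment metadata


def save_cohort(segments: Sequence[EcgSegment], outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sigs = np.stack([s.signal for s in segments])
    np.savez_compressed(outdir / "signals.npz", signals=sigs)
    meta = pd.DataFrame(
        {
            "patient_id": [s.patient_id for s in segments],
            "timestamp": [s.timestamp for s in segments],
            "fs": [s.fs for s in segments],
            "duration": [s.duration for s in segments],
            "true_rhythm": [s.true_rhythm for s in segments],
            "noisy": [s.noisy for s in segments],
            "dropoff": [s.dropoff for s in segments],
        }
    )
    meta.to_csv(outdir / "meta.csv", index=False)
    (outdir / "container.json").write_text(
        json.dumps({"format": "afuq-cohort", "version": 1, "n": len(segments)})
    )


def load_cohort(indir: str | Path) -> list[EcgSegment]:
    indir = Path(indir)
    sigs = np.load(indir / "signals.npz")["signals"]
    meta = pd.read_csv(indir / "meta.csv")
    return [
        EcgSegment(
            signal=sigs[i],
            fs=float(row.fs),
            duration=float(row.duration),
            patient_id=str(row.patient_id),
            timestamp=float(row.timestamp),
            true_rhythm=str(row.true_rhythm),
            noisy=bool(row.noisy),
            dropoff=bool(row.dropoff),
        )
        for i, row in enumerate(meta.itertuples())
    ]
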