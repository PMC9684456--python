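"""Weak-label generation, cohort curation, and class mapping.

Implements the rules used to turn continuous telemetry into a weakly
labelled training pool: rejection of segments containing sensor drop-off,
a minimum 1-hour spacing between per-patient segments, an initial
per-patient cap, and a global per-patient cap at the boxplot upper whisker
(Q3 + 1.5*IQR) of the per-patient count distribution. Weak labels are the
hard-thresholded probabilities of a surrogate classifier trained on an
external labelled cohort; they receive no human verification.

Also provides the external-dataset adaptation steps: mapping source rhythm
class names onto the binary sinus/AF scheme and polyphase resampling from a
source rate (e.g. 500 Hz) down to 240 Hz.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .network import Classifier
from .synthetic import EcgSegment
from .training import predict_proba_batched

__all__ = [
    "CurationRules", "WeakLabelSet", "SINUS_FAMILY", "AF_FAMILY",
    "map_rhythm_classes", "resample_signal", "compute_patient_cap",
    "curate_segments", "build_segment_index", "assign_weak_labels",
    "load_chapman_style_table",
]

#: source rhythm classes mapped to sinus (label 0)
SINUS_FAMILY = frozenset({"Sinus Bradycardia", "Sinus Rhythm", "Sinus Irregularity"})
#: source rhythm classes mapped to AF (label 1); atrial flutter is folded in
AF_FAMILY = frozenset({"Atrial Flutter", "Atrial Fibrillation"})

EXCLUDED = "excluded"


@dataclass(frozen=True)
class CurationRules:
    min_spacing: float = 3600.0       # seconds between per-patient segments
    max_initial_per_patient: int = 1000
    reject_dropoff: bool = True
    apply_whisker_cap: bool = True    # boxplot upper-whisker per-patient cap

    def __post_init__(self) -> None:
        if self.min_spacing <= 0:
            raise ValueError("min_spacing must be positive")


@dataclass
class WeakLabelSet:
    """Surrogate probabilities and hard labels over an unlabelled pool."""

    probabilities: np.ndarray  # p(AF) per segment
    labels: np.ndarray         # hard label, 1 iff probability > threshold
    provenance: str = "surrogate"
    threshold: float = 0.5

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"segment": np.arange(len(self.labels)),
             "probability": self.probabilities,
             "label": self.labels,
             "provenance": self.provenance}
        )


def map_rhythm_classes(source_label: str):
    """Map a source rhythm class name to 0 (sinus family), 1 (AF family), or
    ``"excluded"`` for any other class."""
    if source_label in SINUS_FAMILY:
        return 0
    if source_label in AF_FAMILY:
        return 1
    return EXCLUDED


def resample_signal(signal: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Polyphase resampling of a (leads, samples) array with anti-aliasing.

    Output length is round(samples * fs_out / fs_in).
    """
    if fs_in <= 0 or fs_out <= 0:
        raise ValueError("sampling rates must be positive")
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if not np.isfinite(signal).all():
        raise ValueError("non-finite values in input signal")
    frac = Fraction(fs_out / fs_in).limit_denominator(10000)
    out = sps.resample_poly(signal, frac.numerator, frac.denominator, axis=1,
                            padtype="line")
    n_target = int(round(signal.shape[1] * fs_out / fs_in))
    if out.shape[1] > n_target:
        out = out[:, :n_target]
    elif out.shape[1] < n_target:
        out = np.pad(out, ((0, 0), (0, n_target - out.shape[1])), mode="edge")
    return out


def compute_patient_cap(per_patient_counts: Sequence[int]) -> int:
    """Boxplot upper whisker of the per-patient count distribution.

    Returns floor(Q3 + 1.5*(Q3 - Q1)) with linear-interpolation quartiles.
    """
    counts = np.asarray(per_patient_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("per-patient counts must be non-empty")
    q1, q3 = np.percentile(counts, [25, 75])
    return int(math.floor(q3 + 1.5 * (q3 - q1)))


def build_segment_index(segments: Sequence[EcgSegment]) -> pd.DataFrame:
    """Segment index: one row per segment, keyed by (patient_id, timestamp)."""
    idx = pd.DataFrame(
        {
            "segment": np.arange(len(segments)),
            "patient_id": [s.patient_id for s in segments],
            "timestamp": [s.timestamp for s in segments],
            "dropoff": [s.dropoff for s in segments],
        }
    )
    if (idx["timestamp"] < 0).any():
        raise ValueError("timestamps must be non-negative")
    if idx.duplicated(["patient_id", "timestamp"]).any():
        raise ValueError("(patient_id, timestamp) pairs must be unique")
    return idx


def _greedy_spacing(ts: np.ndarray, min_spacing: float) -> np.ndarray:
    """Keep the first segment, then each next one at least min_spacing later."""
    keep = np.zeros(ts.size, dtype=bool)
    last = -np.inf
    for i, t in enumerate(ts):
        if t - last >= min_spacing or not np.isfinite(last):
            keep[i] = True
            last = t
    return keep


def curate_segments(index: pd.DataFrame, rules: CurationRules | None = None
                    ) -> pd.DataFrame:
    """Apply the curation filters and return the surviving subset of ``index``.

    Order: drop-off rejection, per-patient minimum spacing (greedy in time
    order, keep-first), per-patient truncation at ``max_initial_per_patient``,
    then the global per-patient boxplot-whisker cap. The whisker cap is
    re-applied until the count distribution is a fixed point, which makes the
    whole curation idempotent. The empty index passes through unchanged.
    """
    rules = rules or CurationRules()
    out = index.copy()
    if out.empty:
        return out
    if rules.reject_dropoff:
        out = out[~out["dropoff"].astype(bool)]
    out = out.sort_values(["patient_id", "timestamp"], kind="mergesort")
    kept = []
    for _, grp in out.groupby("patient_id", sort=False):
        keep = _greedy_spacing(grp["timestamp"].to_numpy(float), rules.min_spacing)
        kept.append(grp[keep].head(rules.max_initial_per_patient))
    out = pd.concat(kept) if kept else out.iloc[:0]
    if rules.apply_whisker_cap and not out.empty:
        while True:
            counts = out.groupby("patient_id", sort=False).size()
            cap = compute_patient_cap(counts.to_numpy())
            if (counts <= cap).all():
                break
            out = out.groupby("patient_id", sort=False, group_keys=False).head(cap)
    return out.reset_index(drop=True)


def assign_weak_labels(surrogate: Classifier, pool: Sequence[EcgSegment] | np.ndarray,
                       threshold: float = 0.5, provenance: str = "surrogate"
                       ) -> WeakLabelSet:
    """Label every pool segment with the surrogate's deterministic p(AF).

    The hard label is 1 iff probability strictly exceeds the threshold; a
    probability exactly at the threshold resolves to sinus (negative class).
    """
    if isinstance(pool, np.ndarray):
        signals = pool
    else:
        if len(pool) == 0:
            raise ValueError("pool must be non-empty")
        signals = np.stack([s.signal for s in pool])
    probs = predict_proba_batched(surrogate, signals)
    labels = (probs > threshold).astype(np.int64)
    return WeakLabelSet(probabilities=probs, labels=labels,
                        provenance=provenance, threshold=threshold)


def load_chapman_style_table(meta: pd.DataFrame, label_column: str = "Rhythm"
                             ) -> pd.DataFrame:
    """Adapter step for a Chapman-style metadata table: apply the class
    mapping and drop excluded rows; adds a ``binary_label`` column.

    Signals from such a release are 12-lead at 500 Hz; select leads
    {I, II, III, V1} and pass each signal through ``resample_signal`` to
    240 Hz before classification.
    """
    mapped = meta[label_column].map(map_rhythm_classes)
    out = meta[mapped != EXCLUDED].copy()
    out["binary_label"] = mapped[mapped != EXCLUDED].astype(int)
    return out.reset_index(drop=True)
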