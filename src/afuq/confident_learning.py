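"""Confident learning: estimating which observed labels are likely wrong.

Given a model's predicted class probabilities and a set of observed (weak)
labels, the per-class confidence threshold t_j is the mean predicted
probability of class j over the samples observed-labelled j. A sample is
confidently assigned to the class with the highest predicted probability
among classes whose threshold it meets (p_j >= t_j); samples meeting no
threshold are unassigned. Aggregating these assignments against the observed
labels yields the 2x2 confident joint C[observed, estimated-true]; its
off-diagonal entries are the candidate label errors, which are pruned from
training.

Cleaning runs on a fixed epoch schedule (every 3 epochs by default) using
out-of-loop deterministic predictions on the currently active samples;
removals are cumulative and permanent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .training import predict_proba_batched, refresh_batchnorm_stats

__all__ = [
    "ClassThresholds", "ConfidentJoint", "CleaningSchedule",
    "class_thresholds", "confident_joint", "identify_label_issues",
    "cleaning_hook",
]


@dataclass(frozen=True)
class ClassThresholds:
    t: tuple          # per-class mean self-confidence (t_0, t_1)
    counts: tuple     # per-class observed-label counts (N_0, N_1)


@dataclass(frozen=True)
class ConfidentJoint:
    C: tuple  # 2x2 counts, rows = observed label, columns = estimated true label

    def matrix(self) -> np.ndarray:
        return np.asarray(self.C, dtype=np.int64)

    @property
    def n_offdiagonal(self) -> int:
        m = self.matrix()
        return int(m.sum() - np.trace(m))


@dataclass(frozen=True)
class CleaningSchedule:
    """Cleaning fires at every ``interval``-th epoch after ``burn_in``.

    ``burn_in`` (default 0: clean from the start of training) delays the
    first round at short desk-scale epoch budgets, where an epoch is a far
    larger fraction of total training than in a long run and pruning with a
    still-immature model removes the wrong samples.
    """

    interval: int = 3
    burn_in: int = 0
    cumulative: bool = True  # removals are permanent

    def __post_init__(self) -> None:
        if self.interval < 1:
            raise ValueError("interval must be >= 1")
        if self.burn_in < 0:
            raise ValueError("burn_in must be >= 0")
        if not self.cumulative:
            raise ValueError("only cumulative pruning is supported")


def _prob_matrix(probs: np.ndarray) -> np.ndarray:
    """Accept p(AF) as a vector or explicit (N, 2) class probabilities."""
    probs = np.asarray(probs, dtype=np.float64)
    if probs.ndim == 1:
        return np.column_stack([1.0 - probs, probs])
    if probs.ndim == 2 and probs.shape[1] == 2:
        return probs
    raise ValueError("probs must be a p(AF) vector or an (N, 2) matrix")


def class_thresholds(probs: np.ndarray, observed: np.ndarray) -> ClassThresholds:
    """t_j = mean predicted probability of class j over samples observed as j."""
    P = _prob_matrix(probs)
    observed = np.asarray(observed, dtype=np.int64)
    if observed.shape[0] != P.shape[0]:
        raise ValueError("probs and observed lengths differ")
    t, counts = [], []
    for j in (0, 1):
        members = observed == j
        n_j = int(members.sum())
        if n_j == 0:
            raise ValueError(f"threshold undefined: no samples observed as class {j}")
        t.append(float(P[members, j].mean()))
        counts.append(n_j)
    return ClassThresholds(t=tuple(t), counts=tuple(counts))


def _confident_assignments(P: np.ndarray, observed: np.ndarray,
                           thresholds: ClassThresholds) -> np.ndarray:
    """Estimated true class per sample, or -1 when no class qualifies.

    Qualification is p_j >= t_j (ties qualify). Among qualifying classes the
    argmax wins; an exact probability tie resolves to the observed label when
    it qualifies.
    """
    t = np.asarray(thresholds.t)
    qualifies = P >= t[None, :]
    masked = np.where(qualifies, P, -np.inf)
    jstar = np.argmax(masked, axis=1)
    jstar[~qualifies.any(axis=1)] = -1
    tie = qualifies.all(axis=1) & (P[:, 0] == P[:, 1])
    jstar[tie] = observed[tie]
    return jstar


def confident_joint(probs: np.ndarray, observed: np.ndarray,
                    thresholds: ClassThresholds | None = None) -> ConfidentJoint:
    """Count matrix C[observed, estimated-true] over confidently assigned samples."""
    P = _prob_matrix(probs)
    observed = np.asarray(observed, dtype=np.int64)
    thresholds = thresholds or class_thresholds(P, observed)
    jstar = _confident_assignments(P, observed, thresholds)
    C = np.zeros((2, 2), dtype=np.int64)
    ok = jstar >= 0
    np.add.at(C, (observed[ok], jstar[ok]), 1)
    return ConfidentJoint(C=tuple(map(tuple, C.tolist())))


def identify_label_issues(joint: ConfidentJoint, probs: np.ndarray,
                          observed: np.ndarray) -> np.ndarray:
    """Indices counted off-diagonal: confidently assigned to a class other
    than their observed label. |issues| equals the off-diagonal sum of C."""
    P = _prob_matrix(probs)
    observed = np.asarray(observed, dtype=np.int64)
    thresholds = class_thresholds(P, observed)
    jstar = _confident_assignments(P, observed, thresholds)
    issues = np.flatnonzero((jstar >= 0) & (jstar != observed))
    if issues.size != joint.n_offdiagonal:
        raise ValueError("joint was not computed from these probs/observed")
    return issues


def cleaning_hook(schedule: CleaningSchedule | None = None):
    """Build a training hook that prunes likely-mislabelled samples.

    Every ``interval``-th epoch the hook computes deterministic (dropout-off)
    probabilities on the currently active training samples, constructs the
    confident joint, and deactivates the off-diagonal samples. A round that
    would empty either class is skipped with a warning. Each executed round
    is appended to ``hook.rounds`` (epoch, flagged count, cumulative
    removed, confident-joint entries) for the cleaning report.
    """
    schedule = schedule or CleaningSchedule()
    removed_total = [0]

    def hook(model, data, candidate_idx, epoch) -> np.ndarray:
        if epoch <= schedule.burn_in or epoch % schedule.interval != 0:
            return np.empty(0, dtype=int)
        candidate_idx = np.asarray(candidate_idx, dtype=int)
        observed = data.labels[candidate_idx]
        if np.unique(observed).size < 2:
            warnings.warn("cleaning skipped: only one class active")
            return np.empty(0, dtype=int)
        # probe with dropout inactive; re-centre the normalization statistics
        # on the deterministic activation distribution first
        refresh_batchnorm_stats(model, data.signals[candidate_idx],
                                which=("det",))
        probs = predict_proba_batched(model, data.signals[candidate_idx])
        joint = confident_joint(probs, observed)
        issues = identify_label_issues(joint, probs, observed)
        C = joint.matrix()
        removed_total[0] += issues.size
        hook.rounds.append({
            "epoch": int(epoch), "flagged": int(issues.size),
            "cumulative_removed": int(removed_total[0]),
            "C00": int(C[0, 0]), "C01": int(C[0, 1]),
            "C10": int(C[1, 0]), "C11": int(C[1, 1]),
        })
        if issues.size:
            keep = np.ones(candidate_idx.size, dtype=bool)
            keep[issues] = False
            for cls in (0, 1):
                if not (observed[keep] == cls).any():
                    warnings.warn(
                        f"cleaning round at epoch {epoch} skipped: would empty class {cls}"
                    )
                    return np.empty(0, dtype=int)
        return candidate_idx[issues]

    hook.rounds = []
    return hook
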