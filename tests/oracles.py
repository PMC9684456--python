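"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written directly from the definitions as plain loops,
deliberately sharing no code with the package.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import find_peaks


# --------------------------------------------------------------------------
# waveform rhythm oracle


def detect_r_peaks(segment, min_separation_s: float = 0.25) -> np.ndarray:
    """R-peak sample indices on lead I: local maxima above half the maximum
    with a minimum separation."""
    x = segment.signal[0]
    peaks, _ = find_peaks(x, height=0.5 * float(x.max()),
                          distance=int(min_separation_s * segment.fs))
    return peaks


def rr_cv(segment) -> float:
    """Coefficient of variation of detected RR intervals (NaN if < 3 peaks)."""
    peaks = detect_r_peaks(segment)
    if peaks.size < 3:
        return float("nan")
    rr = np.diff(peaks) / segment.fs
    return float(rr.std() / rr.mean())


def rr_cv_classify(segment, threshold: float = 0.08) -> str:
    """Simple AF-vs-sinus call from RR irregularity alone."""
    return "af" if rr_cv(segment) > threshold else "sinus"


def rr_cv_probability(segment, threshold: float = 0.08, sharpness: float = 25.0,
                      rng: np.random.Generator | None = None,
                      jitter: float = 0.0) -> float:
    """Soft p(AF) from the RR-CV oracle (logistic in the CV), optionally
    jittered to emulate an imperfect but near-oracle model."""
    cv = rr_cv(segment)
    if np.isnan(cv):
        return 0.5
    z = sharpness * (cv - threshold)
    if jitter and rng is not None:
        z += rng.normal(0.0, jitter)
    return float(1.0 / (1.0 + np.exp(-z)))


# --------------------------------------------------------------------------
# metric oracles (plain loops)


def brier_bf(p, y) -> float:
    total = 0.0
    for pi, yi in zip(p, y):
        total += (pi - yi) ** 2
    return total / len(p)


def nll_bf(p, y, eps: float = 1e-7) -> float:
    total = 0.0
    for pi, yi in zip(p, y):
        pi = min(max(pi, eps), 1 - eps)
        total += -(yi * np.log(pi) + (1 - yi) * np.log(1 - pi))
    return total / len(p)


def ece_bf(p, y, n_bins: int = 10) -> float:
    """Equal-width bins, right-open except the last."""
    n = len(p)
    total = 0.0
    for b in range(n_bins):
        lo, hi = b / n_bins, (b + 1) / n_bins
        if b == n_bins - 1:
            members = [i for i in range(n) if lo <= p[i] <= hi]
        else:
            members = [i for i in range(n) if lo <= p[i] < hi]
        if not members:
            continue
        acc = sum(y[i] for i in members) / len(members)
        conf = sum(p[i] for i in members) / len(members)
        total += len(members) / n * abs(acc - conf)
    return total


def confusion_bf(p, y, threshold=0.5):
    tp = sum(1 for pi, yi in zip(p, y) if pi > threshold and yi == 1)
    fp = sum(1 for pi, yi in zip(p, y) if pi > threshold and yi == 0)
    fn = sum(1 for pi, yi in zip(p, y) if pi <= threshold and yi == 1)
    tn = sum(1 for pi, yi in zip(p, y) if pi <= threshold and yi == 0)
    return tp, fp, fn, tn


def mann_whitney_u_bf(x, y) -> float:
    """U for the first sample by explicit pair counting with half-credit ties."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def holm_bf(p_values, alpha):
    """Step-down Holm by explicit sorting."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    reject = [False] * m
    for rank, i in enumerate(order):
        if p_values[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


# --------------------------------------------------------------------------
# confident-learning oracle


def confident_learning_bf(p_af, observed):
    """Thresholds, confident joint and issue set by explicit loops.

    Returns (t, C, issues): per-class mean self-confidence, the 2x2 joint
    (rows = observed, columns = estimated true) and the sorted indices
    assigned off-diagonal. Ties follow the documented rules: classes
    qualify at p_j >= t_j, the qualifying argmax wins, and an exact
    probability tie resolves to the observed label.
    """
    n = len(observed)
    probs = [[1.0 - p_af[i], p_af[i]] for i in range(n)]
    t = []
    for j in (0, 1):
        members = [i for i in range(n) if observed[i] == j]
        assert members, f"class {j} absent"
        # arithmetic mean via the same primitive as production code so that
        # knife-edge p >= t ties are decided on identical float values
        t.append(float(np.mean([probs[i][j] for i in members])))
    C = [[0, 0], [0, 0]]
    issues = []
    for i in range(n):
        qualifying = [j for j in (0, 1) if probs[i][j] >= t[j]]
        if not qualifying:
            continue
        if len(qualifying) == 2 and probs[i][0] == probs[i][1]:
            jstar = observed[i]
        else:
            jstar = max(qualifying, key=lambda j: probs[i][j])
        C[observed[i]][jstar] += 1
        if jstar != observed[i]:
            issues.append(i)
    return t, C, issues
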