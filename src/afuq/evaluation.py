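"""Classification, calibration, agreement and group-comparison statistics.

Classification metrics (F1, PPV/precision, sensitivity/recall, specificity)
come from the 2x2 confusion table at a fixed decision threshold. Calibration
is quantified three ways: the Brier score (mean squared difference between
p(AF) and the binary outcome), the negative log likelihood (mean binary
cross-entropy), and the expected calibration error

    ECE = sum_b |b|/N * |acc(b) - conf(b)|

over B equal-width probability bins (right-open except the last), where
acc(b) is the positive-class prevalence and conf(b) the mean predicted
probability in bin b. Group comparisons of uncertainty distributions use the
two-tailed Mann-Whitney U test (half-credit ties; exact null enumeration for
small samples, otherwise a tie-corrected normal approximation with
continuity correction) with step-down Holm adjustment across each family of
comparisons. Cohen's kappa quantifies inter-rater agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as spstats

from .uncertainty import PredictionSet

__all__ = [
    "MetricsReport", "GroupComparison", "classification_metrics", "brier",
    "nll", "ece", "confidence_count_curve", "cohen_kappa", "mann_whitney_u",
    "holm_correct", "compare_uncertainty_groups", "metrics_report",
]

_EPS = 1e-7

GROUPINGS = ("clean_vs_noisy", "id_vs_ood", "sinus_vs_abstain", "af_vs_abstain")


class UndefinedMetricError(ValueError):
    pass


@dataclass
class MetricsReport:
    model: str
    uncertainty_mode: str
    f1: float
    ppv: float
    sensitivity: float
    specificity: float
    ece: float
    brier: float
    nll: float

    def to_row(self) -> dict:
        return {
            "Model": self.model, "Uncertainty method": self.uncertainty_mode,
            "F1": self.f1, "PPV": self.ppv, "Sensitivity": self.sensitivity,
            "Specificity": self.specificity, "ECE": self.ece,
            "Brier": self.brier, "NLL": self.nll,
        }


@dataclass
class GroupComparison:
    name: str
    u_statistic: float
    p_value: float
    n1: int
    n2: int
    reject: bool | None = None  # Holm-corrected decision at family level


def _split(preds: PredictionSet):
    p = np.asarray(preds.mean, dtype=float)
    y = np.asarray(preds.labels)
    return p, y


def classification_metrics(preds: PredictionSet, threshold: float = 0.5
                           ) -> tuple[float, float, float, float]:
    """(F1, PPV, sensitivity, specificity) at the given decision threshold.

    OOD segments (label -1) are excluded; requires both classes present.
    """
    p, y = _split(preds)
    keep = y >= 0
    p, y = p[keep], y[keep]
    if not ((y == 0).any() and (y == 1).any()):
        raise UndefinedMetricError(
            "classification metrics undefined: both classes must be present"
        )
    yhat = (p > threshold).astype(int)
    tp = int(((yhat == 1) & (y == 1)).sum())
    fp = int(((yhat == 1) & (y == 0)).sum())
    fn = int(((yhat == 0) & (y == 1)).sum())
    tn = int(((yhat == 0) & (y == 0)).sum())
    ppv = tp / (tp + fp) if tp + fp else 0.0
    sens = tp / (tp + fn)
    spec = tn / (tn + fp)
    f1 = 2 * ppv * sens / (ppv + sens) if ppv + sens else 0.0
    return f1, ppv, sens, spec


def brier(preds: PredictionSet) -> float:
    """Mean squared difference between p(AF) and the binary label."""
    p, y = _split(preds)
    keep = y >= 0
    if not keep.any():
        raise UndefinedMetricError("Brier score needs labelled samples")
    return float(np.mean((p[keep] - y[keep]) ** 2))


def nll(preds: PredictionSet) -> float:
    """Mean binary cross-entropy with the training clamp."""
    p, y = _split(preds)
    keep = y >= 0
    if not keep.any():
        raise UndefinedMetricError("NLL needs labelled samples")
    pc = np.clip(p[keep], _EPS, 1 - _EPS)
    yk = y[keep].astype(float)
    return float(-np.mean(yk * np.log(pc) + (1 - yk) * np.log1p(-pc)))


def ece(preds: PredictionSet, n_bins: int = 10) -> tuple[float, pd.DataFrame]:
    """Expected calibration error with its reliability-curve bin table.

    Bins are equal-width over [0, 1], right-open except the last (closed at
    1); empty bins contribute zero. The bin table has columns bin_lo, bin_hi,
    count, acc, conf (acc/conf are NaN for empty bins).
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    p, y = _split(preds)
    keep = y >= 0
    p, y = p[keep], y[keep].astype(float)
    n = p.size
    bin_idx = np.minimum((p * n_bins).astype(int), n_bins - 1)
    rows = []
    total = 0.0
    for b in range(n_bins):
        members = bin_idx == b
        cnt = int(members.sum())
        if cnt:
            acc = float(y[members].mean())
            conf = float(p[members].mean())
            total += cnt / n * abs(acc - conf)
        else:
            acc = conf = np.nan
        rows.append({"bin_lo": b / n_bins, "bin_hi": (b + 1) / n_bins,
                     "count": cnt, "acc": acc, "conf": conf})
    return total, pd.DataFrame(rows)


def confidence_count_curve(preds: PredictionSet,
                           thresholds: np.ndarray | None = None) -> pd.DataFrame:
    """Number of positive-label samples predicted strictly above each threshold."""
    p, y = _split(preds)
    pos = p[y == 1]
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 11)
    counts = [int((pos > t).sum()) for t in thresholds]
    return pd.DataFrame({"threshold": np.asarray(thresholds, float), "count": counts})


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement (p_o - p_e) / (1 - p_e) with
    marginal-product expected agreement."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("label vectors must have equal length")
    cats = np.union1d(np.unique(a), np.unique(b))
    n = a.size
    po = float(np.mean(a == b))
    pe = sum(float(np.mean(a == c)) * float(np.mean(b == c)) for c in cats)
    if pe == 1.0:
        raise UndefinedMetricError("kappa undefined: expected agreement is 1")
    return (po - pe) / (1.0 - pe)


# ---------------------------------------------------------------------------
# Mann-Whitney U


def _exact_u_sf_cdf(u: float, n1: int, n2: int) -> tuple[float, float]:
    """P(U <= u) and P(U >= u) under the exact tie-free null distribution.

    Uses the classic recurrence c(n, m, u) = c(n-1, m, u-m) + c(n, m-1, u)
    for the number of arrangements of n x's among m y's with U = u.
    """
    max_u = n1 * n2
    # row[m] holds the count vector over u for (current n, m)
    rows = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
    for m in range(n2 + 1):
        rows[m][0] = 1.0  # n = 0
    for _ in range(1, n1 + 1):
        prev = rows
        rows = [np.zeros(max_u + 1) for _ in range(n2 + 1)]
        rows[0][0] = 1.0  # m = 0
        for m in range(1, n2 + 1):
            shifted = np.zeros(max_u + 1)
            shifted[m:] = prev[m][: max_u + 1 - m]
            rows[m] = shifted + rows[m - 1]
    pmf = rows[n2]
    pmf = pmf / pmf.sum()
    lo = int(np.floor(u))
    hi = int(np.ceil(u))
    cdf = float(pmf[: lo + 1].sum())
    sf = float(pmf[hi:].sum())
    return cdf, sf


def mann_whitney_u(x, y, exact_limit: int = 400) -> GroupComparison:
    """Two-tailed Mann-Whitney U test on two independent samples.

    U counts pairs (x_i, y_j) with x_i > y_j, with half credit for ties. The
    two-tailed p-value uses exact enumeration of the null distribution when
    n1*n2 <= ``exact_limit`` and the data are tie-free, otherwise the
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n1, n2 = x.size, y.size
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    u = float(gt) + 0.5 * float(eq)

    pooled = np.concatenate([x, y])
    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = (tie_counts > 1).any()
    if not has_ties and n1 * n2 <= exact_limit:
        cdf, sf = _exact_u_sf_cdf(u, n1, n2)
        p = min(1.0, 2.0 * min(cdf, sf))
    else:
        mu = n1 * n2 / 2.0
        n = n1 + n2
        tie_term = ((tie_counts ** 3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12.0 * ((n + 1) - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            d = u - mu
            z = (d - 0.5 * np.sign(d)) / np.sqrt(sigma2)
            p = min(1.0, 2.0 * float(spstats.norm.sf(abs(z))))
    return GroupComparison(name="mann_whitney", u_statistic=u, p_value=p,
                           n1=n1, n2=n2)


def holm_correct(p_values, alpha: float = 0.01) -> np.ndarray:
    """Step-down Holm decisions at family level ``alpha`` (monotone)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    reject = np.zeros(m, dtype=bool)
    for rank, i in enumerate(order):
        if p[i] <= alpha / (m - rank):
            reject[i] = True
        else:
            break
    return reject


def compare_uncertainty_groups(preds: PredictionSet,
                               groupings=GROUPINGS,
                               alpha: float = 0.01) -> list[GroupComparison]:
    """Mann-Whitney comparisons of uncertainty values between named groups,
    Holm-corrected across the requested family.

    Groupings: clean_vs_noisy (in-distribution segments by noise flag),
    id_vs_ood, sinus_vs_abstain, af_vs_abstain (abstain = OOD analog). An
    empty group yields a comparison with p=NaN, excluded from the family.
    """
    if isinstance(groupings, str):
        groupings = (groupings,)
    u = np.asarray(preds.std, dtype=float)
    sel = {
        "clean_vs_noisy": (~preds.noisy & ~preds.ood, preds.noisy & ~preds.ood),
        "id_vs_ood": (~preds.ood, preds.ood),
        "sinus_vs_abstain": ((preds.labels == 0) & ~preds.ood, preds.ood),
        "af_vs_abstain": ((preds.labels == 1) & ~preds.ood, preds.ood),
    }
    results = []
    for name in groupings:
        if name not in sel:
            raise ValueError(f"unknown grouping {name!r}")
        g1, g2 = sel[name]
        if not g1.any() or not g2.any():
            results.append(GroupComparison(name=name, u_statistic=np.nan,
                                           p_value=np.nan, n1=int(g1.sum()),
                                           n2=int(g2.sum()), reject=None))
            continue
        cmp = mann_whitney_u(u[g1], u[g2])
        cmp.name = name
        results.append(cmp)
    valid = [r for r in results if np.isfinite(r.p_value)]
    if valid:
        decisions = holm_correct([r.p_value for r in valid], alpha=alpha)
        for r, d in zip(valid, decisions):
            r.reject = bool(d)
    return results


def metrics_report(preds: PredictionSet, model_name: str, n_bins: int = 10,
                   threshold: float = 0.5) -> MetricsReport:
    """Bundle all classification and calibration metrics for one
    model x uncertainty-mode configuration."""
    f1, ppv, sens, spec = classification_metrics(preds, threshold)
    e, _ = ece(preds, n_bins)
    return MetricsReport(
        model=model_name, uncertainty_mode=preds.mode, f1=f1, ppv=ppv,
        sensitivity=sens, specificity=spec, ece=e, brier=brier(preds),
        nll=nll(preds),
    )
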