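"""Diagnostic-accuracy statistics: 2x2 tables, group tests, ROC analysis.

Sensitivity, specificity, predictive values and accuracy are computed from
contingency counts with Wilson score confidence intervals (the paper-style
boundary cases 0/n and n/n make Wald intervals degenerate, Wilson does
not). Group comparisons use Pearson's chi-square — falling back to
Fisher's exact test for sparse 2x2 tables — and one-way ANOVA. The ROC
construction uses every distinct observed score as a threshold with
"score >= threshold" as the positive call; the trapezoidal AUC then equals
the tie-corrected Mann-Whitney statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "TwoByTwo",
    "ConfidenceInterval",
    "DiagnosticMetrics",
    "GroupTestResult",
    "ROCResult",
    "make_two_by_two",
    "metrics",
    "wilson_ci",
    "chi_square_test",
    "one_way_anova",
    "roc_curve",
    "binormal_auc",
    "percent_round_half_up",
]


def percent_round_half_up(proportion: float) -> int:
    """Proportion -> whole percent, rounding halves up (0.615 -> 62)."""
    return int(math.floor(proportion * 100.0 + 0.5))


@dataclass(frozen=True)
class TwoByTwo:
    """Contingency counts for a binary criterion against a binary label."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if not isinstance(v, (int, np.integer)) or v < 0:
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def swapped(self) -> "TwoByTwo":
        """Exchange the roles of the two classes (tp<->tn, fp<->fn)."""
        return TwoByTwo(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class ConfidenceInterval:
    lo: float
    hi: float
    level: float = 0.95


@dataclass(frozen=True)
class MetricEstimate:
    """A proportion with its confidence interval; None when undefined."""

    value: Optional[float]
    ci: Optional[ConfidenceInterval]
    numerator: int
    denominator: int

    @property
    def available(self) -> bool:
        return self.value is not None

    @property
    def percent(self) -> Optional[int]:
        if self.value is None:
            return None
        return percent_round_half_up(self.value)


@dataclass(frozen=True)
class DiagnosticMetrics:
    sensitivity: MetricEstimate
    specificity: MetricEstimate
    ppv: MetricEstimate
    npv: MetricEstimate
    accuracy: MetricEstimate
    table: TwoByTwo


@dataclass(frozen=True)
class GroupTestResult:
    statistic: float
    df: Optional[float]
    p_value: float
    test_name: str

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError(f"p-value out of [0, 1]: {self.p_value}")


@dataclass(frozen=True)
class ROCResult:
    thresholds: np.ndarray
    tpr: np.ndarray
    fpr: np.ndarray
    auc: float
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float


def make_two_by_two(
    predictions: Sequence[bool], labels: Sequence[bool]
) -> TwoByTwo:
    """Cross-tabulate Boolean predictions against Boolean labels."""
    preds = np.asarray(predictions, dtype=bool)
    labs = np.asarray(labels, dtype=bool)
    if preds.shape != labs.shape or preds.ndim != 1:
        raise ValueError(
            f"predictions and labels must be equal-length 1-D vectors, "
            f"got shapes {preds.shape} and {labs.shape}"
        )
    if preds.size == 0:
        raise ValueError("empty vectors")
    return TwoByTwo(
        tp=int(np.sum(preds & labs)),
        fp=int(np.sum(preds & ~labs)),
        fn=int(np.sum(~preds & labs)),
        tn=int(np.sum(~preds & ~labs)),
    )


def wilson_ci(successes: int, n: int, confidence: float = 0.95) -> ConfidenceInterval:
    """Wilson score interval for a binomial proportion.

    Closed form: centre (p + z^2/2n) / (1 + z^2/n) with half-width
    z * sqrt(p(1-p)/n + z^2/4n^2) / (1 + z^2/n).
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not (0 <= successes <= n):
        raise ValueError(f"successes out of [0, n]: {successes}/{n}")
    if not (0.0 < confidence < 1.0):
        raise ValueError(f"confidence out of (0, 1): {confidence}")
    z = stats.norm.ppf(0.5 + confidence / 2.0)
    p = successes / n
    denom = 1.0 + z * z / n
    centre = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    # at k = 0 (k = n) the lower (upper) Wilson bound is exactly 0 (1)
    lo = 0.0 if successes == 0 else max(0.0, centre - half)
    hi = 1.0 if successes == n else min(1.0, centre + half)
    return ConfidenceInterval(lo, hi, confidence)


def _estimate(num: int, den: int, confidence: float) -> MetricEstimate:
    if den == 0:
        return MetricEstimate(None, None, num, den)
    return MetricEstimate(num / den, wilson_ci(num, den, confidence), num, den)


def metrics(t: TwoByTwo, confidence: float = 0.95) -> DiagnosticMetrics:
    """Sensitivity, specificity, PPV, NPV and accuracy with Wilson CIs.

    Metrics with a zero denominator are reported as not available rather
    than silently as 0/0.
    """
    if t.total == 0:
        raise ValueError("cannot compute metrics on an empty table")
    return DiagnosticMetrics(
        sensitivity=_estimate(t.tp, t.tp + t.fn, confidence),
        specificity=_estimate(t.tn, t.tn + t.fp, confidence),
        ppv=_estimate(t.tp, t.tp + t.fp, confidence),
        npv=_estimate(t.tn, t.tn + t.fn, confidence),
        accuracy=_estimate(t.tp + t.tn, t.total, confidence),
        table=t,
    )


def chi_square_test(contingency: Sequence[Sequence[float]]) -> GroupTestResult:
    """Pearson chi-square test of independence on an r x c count table.

    For 2x2 tables with any expected count below 5 the test falls back to
    Fisher's exact test (standard sparse-table practice).
    """
    table = np.asarray(contingency, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError(f"need at least a 2x2 table, got shape {table.shape}")
    if np.any(table < 0):
        raise ValueError("negative counts")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate table: a row or column margin is zero")
    expected = stats.contingency.expected_freq(table)
    if table.shape == (2, 2) and np.any(expected < 5):
        _, p = stats.fisher_exact(table.astype(int))
        return GroupTestResult(float("nan"), None, float(p), "fisher_exact")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return GroupTestResult(float(chi2), float(df), float(p), "pearson_chi_square")


def one_way_anova(groups: Sequence[Sequence[float]]) -> GroupTestResult:
    """One-way ANOVA F test across two or more groups of values."""
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least two values")
    f, p = stats.f_oneway(*arrays)
    df_between = len(arrays) - 1
    return GroupTestResult(float(f), float(df_between), float(p), "one_way_anova")


def roc_curve(scores: Sequence[float], labels: Sequence[bool]) -> ROCResult:
    """ROC curve with explicit "higher score = positive" direction.

    Thresholds are the distinct observed scores in decreasing order; a
    call is positive when score >= threshold. The AUC is the trapezoidal
    integral of TPR against FPR, which under this construction equals the
    tie-corrected Mann-Whitney statistic (ties counted one half). The
    Youden cutoff maximises TPR - FPR, ties broken toward the LOWER
    threshold (maximising sensitivity at equal Youden index).
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape or s.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D vectors")
    if not np.all(np.isfinite(s)):
        raise ValueError("scores must be finite")
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")

    order = np.argsort(-s, kind="stable")
    s_sorted = s[order]
    y_sorted = y[order]
    distinct = np.r_[True, np.diff(s_sorted) != 0]
    idx = np.flatnonzero(distinct)
    # cumulative counts at the end of each tie-block
    block_end = np.r_[idx[1:] - 1, s_sorted.size - 1]
    cum_tp = np.cumsum(y_sorted)[block_end]
    cum_fp = np.cumsum(~y_sorted)[block_end]
    thresholds = s_sorted[idx]
    tpr = cum_tp / n_pos
    fpr = cum_fp / n_neg
    # prepend the (0, 0) operating point (threshold above every score)
    tpr_full = np.r_[0.0, tpr]
    fpr_full = np.r_[0.0, fpr]
    auc = float(np.trapezoid(tpr_full, fpr_full))

    j = tpr - fpr
    best = int(np.flatnonzero(j == j.max())[-1])  # descending order -> last = lowest
    return ROCResult(
        thresholds=thresholds,
        tpr=tpr_full,
        fpr=fpr_full,
        auc=auc,
        youden_cutoff=float(thresholds[best]),
        sens_at_cutoff=float(tpr[best]),
        spec_at_cutoff=float(1.0 - fpr[best]),
    )


def binormal_auc(mu_pos: float, sd_pos: float, mu_neg: float, sd_neg: float) -> float:
    """Closed-form AUC for Gaussian score distributions in each class.

    Phi((mu_pos - mu_neg) / sqrt(sd_pos^2 + sd_neg^2)).
    """
    if sd_pos <= 0 or sd_neg <= 0:
        raise ValueError("standard deviations must be positive")
    return float(stats.norm.cdf((mu_pos - mu_neg) / math.hypot(sd_pos, sd_neg)))
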