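"""Diagnostic-validation statistics for index-versus-reference comparisons.

Conventions follow standard FFR practice: an index value less than or
equal to the cutoff calls the vessel ischemic (positive class), with the
invasive reference dichotomised at 0.80.  ROC analysis therefore sweeps
"score <= threshold" classifiers; AUC is the trapezoidal area, identical
to the tie-corrected Mann–Whitney probability on negated scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import InvalidArgumentError

__all__ = [
    "ConfusionMatrix",
    "DiagnosticMetrics",
    "RocResult",
    "BlandAltmanResult",
    "DeLongResult",
    "confusion_metrics",
    "classify",
    "pearson_r",
    "bland_altman",
    "roc_youden",
    "delong_compare",
]


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise InvalidArgumentError("counts must be non-negative")
        if self.total == 0:
            raise InvalidArgumentError("confusion matrix must contain at least one case")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class DiagnosticMetrics:
    """Percentages in [0, 100]; a metric with a zero denominator is None
    (undefined), never silently 0."""

    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None

    def rounded(self, ndigits: int = 1) -> dict[str, float | None]:
        """Display form (1 decimal by default); analysis uses the raw values."""
        return {
            k: (None if v is None else round(v, ndigits))
            for k, v in self.__dict__.items()
        }


@dataclass(frozen=True)
class RocResult:
    auc: float
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    youden_cutoff: float
    youden_j: float


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd_diff: float
    loa_low: float
    loa_high: float
    ci_low_limit: tuple[float, float]
    ci_high_limit: tuple[float, float]
    n: int


@dataclass(frozen=True)
class DeLongResult:
    auc_1: float
    auc_2: float
    z_statistic: float
    p_value: float


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else 100.0 * num / den


def confusion_metrics(cm: ConfusionMatrix) -> DiagnosticMetrics:
    """Accuracy, sensitivity, specificity, PPV and NPV as percentages."""
    return DiagnosticMetrics(
        accuracy=100.0 * (cm.tp + cm.tn) / cm.total,
        sensitivity=_ratio(cm.tp, cm.tp + cm.fn),
        specificity=_ratio(cm.tn, cm.tn + cm.fp),
        ppv=_ratio(cm.tp, cm.tp + cm.fp),
        npv=_ratio(cm.tn, cm.tn + cm.fn),
    )


def classify(
    index_values,
    reference_values,
    index_cutoff: float,
    reference_cutoff: float = 0.80,
) -> ConfusionMatrix:
    """Cross-tabulate index-positive (value <= index cutoff) against
    reference-positive (value <= reference cutoff, default FFR 0.80)."""
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(reference_values, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("index and reference must have equal length")
    ipos = x <= index_cutoff
    rpos = y <= reference_cutoff
    return ConfusionMatrix(
        tp=int(np.sum(ipos & rpos)),
        tn=int(np.sum(~ipos & ~rpos)),
        fp=int(np.sum(ipos & ~rpos)),
        fn=int(np.sum(~ipos & rpos)),
    )


def pearson_r(x, y) -> float:
    """Product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidArgumentError("need n >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        raise InvalidArgumentError("correlation undefined for zero-variance input")
    return float(stats.pearsonr(x, y).statistic)


def bland_altman(x, y) -> BlandAltmanResult:
    """Agreement between two paired measurements.

    Differences d = x - y; limits of agreement = bias +/- 1.96*sd(d)
    (sample sd); each limit's 95% CI uses the classical sd*sqrt(3/n)
    standard error with a t quantile on n-1 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise InvalidArgumentError("x and y must have equal length")
    n = x.size
    if n < 3:
        raise InvalidArgumentError("need n >= 3 paired observations")
    d = x - y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    loa_low, loa_high = bias - 1.96 * sd, bias + 1.96 * sd
    half = float(stats.t.ppf(0.975, n - 1)) * sd * math.sqrt(3.0 / n)
    return BlandAltmanResult(
        bias=bias,
        sd_diff=sd,
        loa_low=loa_low,
        loa_high=loa_high,
        ci_low_limit=(loa_low - half, loa_low + half),
        ci_high_limit=(loa_high - half, loa_high + half),
        n=n,
    )


def roc_youden(index_values, disease_labels) -> RocResult:
    """ROC analysis for a "low index means diseased" marker.

    Candidate thresholds are the sorted unique index values; a case is
    called positive when its value <= threshold.  AUC is the trapezoidal
    area over the resulting (FPR, TPR) staircase, with (0,0) and (1,1)
    anchors.  The Youden-optimal cutoff maximises J = sens + spec - 1;
    ties resolve to the largest threshold.
    """
    x = np.asarray(index_values, dtype=float)
    labels = np.asarray(disease_labels, dtype=int)
    if x.shape != labels.shape:
        raise InvalidArgumentError("values and labels must have equal length")
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise InvalidArgumentError("both classes must be present")
    thresholds = np.unique(x)
    sens = np.array([np.sum((x <= t) & (labels == 1)) / n_pos for t in thresholds])
    spec = np.array([np.sum((x > t) & (labels == 0)) / n_neg for t in thresholds])
    fpr = np.concatenate([[0.0], 1.0 - spec, [1.0]])
    tpr = np.concatenate([[0.0], sens, [1.0]])
    auc = float(np.trapezoid(tpr, fpr))
    j = sens + spec - 1.0
    best = np.flatnonzero(j == j.max())[-1]  # largest maximiser
    return RocResult(
        auc=auc,
        thresholds=thresholds,
        sensitivity=sens,
        specificity=spec,
        youden_cutoff=float(thresholds[best]),
        youden_j=float(j[best]),
    )


def _placements(pos: np.ndarray, neg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong structural components: for each diseased score its mean win
    rate over healthy scores, and vice versa (ties count 1/2)."""
    diff = pos[:, None] - neg[None, :]
    psi = np.where(diff > 0, 1.0, np.where(diff == 0, 0.5, 0.0))
    return psi.mean(axis=1), psi.mean(axis=0)


def delong_compare(scores_1, scores_2, disease_labels) -> DeLongResult:
    """DeLong test comparing two correlated ROC AUCs measured on the same
    cases.

    Orientation matches :func:`roc_youden`: low scores indicate disease,
    so scores are negated before computing the Mann–Whitney kernels.
    Identical score vectors give z = 0, p = 1 by convention.
    """
    s1 = -np.asarray(scores_1, dtype=float)
    s2 = -np.asarray(scores_2, dtype=float)
    labels = np.asarray(disease_labels, dtype=int)
    if not (s1.shape == s2.shape == labels.shape):
        raise InvalidArgumentError("score vectors and labels must have equal length")
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise InvalidArgumentError("both classes must be present")

    v10_1, v01_1 = _placements(s1[pos], s1[~pos])
    v10_2, v01_2 = _placements(s2[pos], s2[~pos])
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())

    def cov(a, b):
        return float(np.cov(a, b, ddof=1)[0, 1]) if a.size > 1 else 0.0

    var = (
        cov(v10_1, v10_1) / m + cov(v01_1, v01_1) / n
        + cov(v10_2, v10_2) / m + cov(v01_2, v01_2) / n
        - 2.0 * (cov(v10_1, v10_2) / m + cov(v01_1, v01_2) / n)
    )
    if var <= 0:
        z, p = 0.0, 1.0
    else:
        z = (auc1 - auc2) / math.sqrt(var)
        p = 2.0 * float(stats.norm.sf(abs(z)))
    return DeLongResult(auc_1=auc1, auc_2=auc2, z_statistic=z, p_value=p)


def auc_variance_delong(scores, disease_labels) -> float:
    """DeLong variance of a single AUC (used for SEs and sanity checks)."""
    s = -np.asarray(scores, dtype=float)
    labels = np.asarray(disease_labels, dtype=int)
    pos = labels == 1
    m, n = int(pos.sum()), int((~pos).sum())
    if m == 0 or n == 0:
        raise InvalidArgumentError("both classes must be present")
    v10, v01 = _placements(s[pos], s[~pos])
    var10 = float(np.var(v10, ddof=1)) if m > 1 else 0.0
    var01 = float(np.var(v01, ddof=1)) if n > 1 else 0.0
    return var10 / m + var01 / n
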