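"""Diagnostic-accuracy statistics.

Everything needed to evaluate an ordinal malignancy score against
histopathological truth on one cohort:

* 2x2 confusion tables with exact-rational metrics (sensitivity,
  specificity, accuracy, PPV, NPV) and the usual one-decimal percent
  display convention (round half up);
* empirical ROC operating points and the Mann-Whitney (midrank-tie) AUC;
* DeLong structural components, variance, and the paired DeLong test for
  two correlated AUCs measured on the same subjects;
* Cohen's kappa for two binary readings, with the Fleiss-Cohen-Everitt
  large-sample variance and the interpretation bands used in the breast-MRI
  reliability literature (< 0.4 bad, 0.4-0.7 good, > 0.7 excellent);
* Pearson chi-square (continuity correction off by default) for comparing
  two proportions.

Malignant is the positive class throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
from scipy import stats as sps

__all__ = [
    "ConfusionTable",
    "MetricSet",
    "AucEstimate",
    "PairedAucComparison",
    "KappaEstimate",
    "ProportionComparison",
    "round_percent",
    "build_confusion",
    "confusion_metrics",
    "roc_points",
    "trapezoid_auc",
    "auc_mann_whitney",
    "delong_components",
    "auc_with_ci",
    "delong_paired_test",
    "cohen_kappa",
    "chi2_2x2",
]


def round_percent(numerator: int, denominator: int) -> float:
    """Half-up rounding of 100 * num/den to one decimal (display convention)."""
    if denominator == 0:
        raise ZeroDivisionError("round_percent with zero denominator")
    scaled = Fraction(1000 * numerator, denominator)
    # round half UP (not banker's): floor(x + 1/2)
    return math.floor(scaled + Fraction(1, 2)) / 10


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class Metric:
    """One diagnostic proportion: exact fraction plus percent display."""

    numerator: int
    denominator: int

    @property
    def defined(self) -> bool:
        return self.denominator > 0

    @property
    def value(self) -> Fraction | None:
        return Fraction(self.numerator, self.denominator) if self.defined else None

    @property
    def display(self) -> float | None:
        return round_percent(self.numerator, self.denominator) if self.defined else None

    def __str__(self) -> str:
        if not self.defined:
            return "undefined"
        return f"{self.display}% ({self.numerator}/{self.denominator})"


@dataclass(frozen=True)
class MetricSet:
    sensitivity: Metric
    specificity: Metric
    accuracy: Metric
    ppv: Metric
    npv: Metric

    def as_dict(self) -> dict:
        out = {}
        for name in ("sensitivity", "specificity", "accuracy", "ppv", "npv"):
            m: Metric = getattr(self, name)
            out[name] = {
                "numerator": m.numerator,
                "denominator": m.denominator,
                "percent": m.display,
            }
        return out


def build_confusion(predicted_positive, truth_malignant) -> ConfusionTable:
    pred = np.asarray(predicted_positive, dtype=bool)
    truth = np.asarray(truth_malignant, dtype=bool)
    if pred.shape != truth.shape or pred.ndim != 1 or pred.size == 0:
        raise ValueError("prediction and truth must be equal-length non-empty 1-d vectors")
    return ConfusionTable(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def confusion_metrics(t: ConfusionTable) -> MetricSet:
    return MetricSet(
        sensitivity=Metric(t.tp, t.tp + t.fn),
        specificity=Metric(t.tn, t.tn + t.fp),
        accuracy=Metric(t.tp + t.tn, t.n),
        ppv=Metric(t.tp, t.tp + t.fp),
        npv=Metric(t.tn, t.tn + t.fn),
    )


def _split_classes(scores, truth):
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(truth, dtype=bool)
    if scores.shape != truth.shape or scores.ndim != 1:
        raise ValueError("scores and truth must be equal-length 1-d vectors")
    x = scores[truth]  # malignant
    y = scores[~truth]  # benign
    if x.size == 0 or y.size == 0:
        raise ValueError("both classes must be present")
    return x, y


def roc_points(scores, truth) -> np.ndarray:
    """Empirical ROC operating points for thresholds "score > c".

    One point per distinct score value c (in decreasing c order), plus the
    (0, 0) and (1, 1) endpoints; returned as an array of (fpr, tpr) rows,
    monotone non-decreasing in both coordinates.
    """
    x, y = _split_classes(scores, truth)
    m, n = x.size, y.size
    pts = [(0.0, 0.0)]
    for c in sorted(np.unique(np.concatenate([x, y])))[::-1]:
        pt = (float(np.sum(y > c)) / n, float(np.sum(x > c)) / m)
        if pt != pts[-1]:
            pts.append(pt)
    if pts[-1] != (1.0, 1.0):
        pts.append((1.0, 1.0))
    return np.array(pts)


def trapezoid_auc(points: np.ndarray) -> float:
    fpr, tpr = points[:, 0], points[:, 1]
    return float(np.trapezoid(tpr, fpr))


def auc_mann_whitney(scores, truth) -> float:
    """AUC as the Mann-Whitney probability P(X > Y) + 0.5 P(X = Y),
    X malignant scores, Y benign scores (midrank tie handling)."""
    x, y = _split_classes(scores, truth)
    m, n = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    rank_sum_x = ranks[:m].sum()
    return float((rank_sum_x - m * (m + 1) / 2) / (m * n))


def _structural_components(scores, truth):
    """DeLong V10 (per malignant case) and V01 (per benign case) components."""
    x, y = _split_classes(scores, truth)
    # psi matrix via broadcasting; cohorts here are small (hundreds)
    psi = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    return psi.mean(axis=1), psi.mean(axis=0)  # V10 (len m), V01 (len n)


def delong_components(scores, truth) -> tuple[float, float]:
    """AUC and its DeLong variance S10/m + S01/n (sample variances, ddof=1)."""
    v10, v01 = _structural_components(scores, truth)
    m, n = v10.size, v01.size
    if m < 2 or n < 2:
        raise ValueError("DeLong variance needs at least 2 cases per class")
    auc = float(v10.mean())
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


@dataclass(frozen=True)
class AucEstimate:
    auc: float
    se: float
    ci95: tuple[float, float]


def auc_with_ci(scores, truth) -> AucEstimate:
    """Normal-theory 95% CI on the DeLong SE, truncated to [0, 1]."""
    auc, var = delong_components(scores, truth)
    se = math.sqrt(max(var, 0.0))
    lo, hi = max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se)
    return AucEstimate(auc=auc, se=se, ci95=(lo, hi))


@dataclass(frozen=True)
class PairedAucComparison:
    auc1: float
    auc2: float
    covariance: float
    z: float
    p: float


def delong_paired_test(scores1, scores2, truth) -> PairedAucComparison:
    """DeLong's test for two correlated AUCs measured on the same lesions.

    Covariance comes from the paired structural components:
    cov = S10(1,2)/m + S01(1,2)/n. Two-sided normal p-value on
    z = (auc1 - auc2) / sqrt(var1 + var2 - 2 cov).
    """
    s1 = np.asarray(scores1, dtype=float)
    s2 = np.asarray(scores2, dtype=float)
    t = np.asarray(truth, dtype=bool)
    if not (s1.shape == s2.shape == t.shape):
        raise ValueError("scores1, scores2 and truth must have identical shape")
    v10_1, v01_1 = _structural_components(s1, t)
    v10_2, v01_2 = _structural_components(s2, t)
    m, n = v10_1.size, v01_1.size
    if m < 2 or n < 2:
        raise ValueError("DeLong test needs at least 2 cases per class")
    auc1, auc2 = float(v10_1.mean()), float(v10_2.mean())
    var1 = np.var(v10_1, ddof=1) / m + np.var(v01_1, ddof=1) / n
    var2 = np.var(v10_2, ddof=1) / m + np.var(v01_2, ddof=1) / n
    cov = float(np.cov(v10_1, v10_2, ddof=1)[0, 1] / m + np.cov(v01_1, v01_2, ddof=1)[0, 1] / n)
    denom2 = var1 + var2 - 2 * cov
    if denom2 <= 0:
        if math.isclose(auc1, auc2, abs_tol=1e-12):
            return PairedAucComparison(auc1, auc2, cov, 0.0, 1.0)
        raise ValueError("degenerate paired comparison: zero variance but unequal AUCs")
    z = (auc1 - auc2) / math.sqrt(denom2)
    p = float(2 * sps.norm.sf(abs(z)))
    return PairedAucComparison(auc1, auc2, cov, float(z), p)


@dataclass(frozen=True)
class KappaEstimate:
    kappa: float
    se: float
    ci95: tuple[float, float]
    band: str


def _kappa_band(kappa: float) -> str:
    if kappa < 0.4:
        return "bad"
    if kappa <= 0.7:
        return "good"
    return "excellent"


def cohen_kappa(ratings1, ratings2) -> KappaEstimate:
    """Unweighted Cohen's kappa between two binary readings.

    SE is the Fleiss-Cohen-Everitt large-sample standard error of the point
    estimate; the 95% CI is kappa +/- 1.96 SE. Two constant identical
    readings (chance agreement 1) are perfect agreement by convention.
    """
    r1 = np.asarray(ratings1, dtype=bool)
    r2 = np.asarray(ratings2, dtype=bool)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size < 2:
        raise ValueError("ratings must be equal-length 1-d vectors of length >= 2")
    n = r1.size
    # 2x2 agreement proportions p[i][j] = P(rater1 = i, rater2 = j)
    p = np.array(
        [
            [np.sum(~r1 & ~r2), np.sum(~r1 & r2)],
            [np.sum(r1 & ~r2), np.sum(r1 & r2)],
        ],
        dtype=float,
    ) / n
    row = p.sum(axis=1)
    col = p.sum(axis=0)
    po = float(np.trace(p))
    pe = float(row @ col)
    if math.isclose(pe, 1.0, abs_tol=1e-15):
        kappa = 1.0 if math.isclose(po, 1.0, abs_tol=1e-15) else 0.0
        return KappaEstimate(kappa, 0.0, (kappa, kappa), _kappa_band(kappa))
    kappa = (po - pe) / (1 - pe)
    # Fleiss, Cohen & Everitt (1969) asymptotic variance of the estimate
    a = sum(
        p[i, i] * (1 - (row[i] + col[i]) * (1 - kappa)) ** 2 for i in range(2)
    )
    b = (1 - kappa) ** 2 * sum(
        p[i, j] * (col[i] + row[j]) ** 2 for i in range(2) for j in range(2) if i != j
    )
    c = (kappa - pe * (1 - kappa)) ** 2
    var = (a + b - c) / (n * (1 - pe) ** 2)
    se = math.sqrt(max(var, 0.0))
    ci = (max(-1.0, kappa - 1.96 * se), min(1.0, kappa + 1.96 * se))
    return KappaEstimate(float(kappa), se, ci, _kappa_band(float(kappa)))


@dataclass(frozen=True)
class ProportionComparison:
    chi2: float
    df: int
    p: float


def chi2_2x2(table, continuity_correction: bool = False) -> ProportionComparison:
    """Pearson chi-square on a 2x2 table, df = 1, two-sided.

    The continuity (Yates) correction is OFF by default; pass
    ``continuity_correction=True`` to enable it.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be a non-negative 2x2 array")
    n = t.sum()
    row = t.sum(axis=1)
    col = t.sum(axis=0)
    if n < 1 or (row == 0).any() or (col == 0).any():
        raise ValueError("chi-square undefined: zero marginal")
    expected = np.outer(row, col) / n
    diff = np.abs(t - expected)
    if continuity_correction:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1)) if chi2 > 0 else 1.0
    return ProportionComparison(chi2=chi2, df=1, p=p)
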