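"""Discrimination and calibration metrics for the nested risk models.

AUROC is the Mann-Whitney concordance probability (ties count one half);
its variance and confidence interval, and the paired test comparing two
correlated ROC curves fitted on the same subjects, use DeLong's structural
components (placement values). The scaled Brier score is
1 - Brier / (pbar*(1-pbar)), i.e. squared-error loss relative to a
constant-prevalence reference model: 1 for perfect predictions, 0 for the
reference.

Caveat (documented, matching common practice): the DeLong test is known to
be anticonservative when applied in-sample to nested models fitted on the
same data; metrics here are apparent (in-sample) performance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class PerformanceResult:
    auc: float
    auc_variance: float
    ci_low: float
    ci_high: float
    n: int
    n_cases: int
    model: str | None = None


@dataclass
class ROCComparison:
    auc_a: float
    auc_b: float
    delta: float  # auc_b - auc_a
    variance: float
    z: float
    p_value: float
    degenerate: bool = False  # variance 0 (e.g. self-comparison)


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels differ in length")
    uniq = np.unique(labels)
    if not np.all(np.isin(uniq, (0, 1, True, False))):
        raise ValueError("labels must be binary 0/1")
    labels = labels.astype(int)
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")
    return scores, labels


def _midrank(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """DeLong placement values V10 (per case) and V01 (per control)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_r = _midrank(np.concatenate([pos, neg]))
    r_pos = _midrank(pos)
    r_neg = _midrank(neg)
    v10 = (all_r[:m] - r_pos) / n  # P(score_control < score_case) per case
    v01 = 1.0 - (all_r[m:] - r_neg) / m
    auc = v10.mean()  # == v01.mean()
    return auc, v10, v01


def auc_with_ci(scores, labels, alpha: float = 0.05,
                model: str | None = None) -> PerformanceResult:
    """AUROC with DeLong variance and a normal-approximation CI.

    The CI is clipped to [0, 1]; a degenerate variance (perfect or
    all-tied scores) yields a zero-width interval at the estimate.
    """
    scores, labels = _validate(scores, labels)
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    z = stats.norm.ppf(1 - alpha / 2)
    half = z * np.sqrt(max(var, 0.0))
    return PerformanceResult(
        auc=float(auc), auc_variance=float(var),
        ci_low=float(max(0.0, auc - half)), ci_high=float(min(1.0, auc + half)),
        n=m + n, n_cases=m, model=model,
    )


def compare_auc_delong(scores_a, scores_b, labels) -> ROCComparison:
    """Paired DeLong test for two score vectors on the same subjects.

    delta = AUC(b) - AUC(a); two-sided normal p from the
    covariance-adjusted variance of delta. If that variance is zero (e.g.
    comparing a model to itself) the comparison is flagged degenerate and
    p = 1 when delta = 0.
    """
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    if scores_a.shape != scores_b.shape:
        raise ValueError("paired score vectors differ in length")
    _, labels_arr = _validate(scores_a, labels)
    auc_a, va10, va01 = _structural_components(scores_a, labels_arr)
    auc_b, vb10, vb01 = _structural_components(scores_b, labels_arr)
    m, n = len(va10), len(va01)
    s10 = np.cov(np.vstack([va10, vb10]), ddof=1) if m > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([va01, vb01]), ddof=1) if n > 1 else np.zeros((2, 2))
    cov = s10 / m + s01 / n
    contrast = np.array([-1.0, 1.0])
    var = float(contrast @ cov @ contrast)
    delta = float(auc_b - auc_a)
    if var <= 0:
        return ROCComparison(float(auc_a), float(auc_b), delta, 0.0,
                             z=0.0 if delta == 0 else np.inf,
                             p_value=1.0 if delta == 0 else 0.0,
                             degenerate=True)
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return ROCComparison(float(auc_a), float(auc_b), delta, var,
                         z=float(z), p_value=float(p))


def scaled_brier(scores, labels) -> float:
    """1 - mean squared error relative to the prevalence reference model."""
    scores, labels = _validate(scores, labels)
    if np.any((scores < 0) | (scores > 1)):
        raise ValueError("scores must be probabilities in [0, 1]")
    pbar = labels.mean()
    denom = pbar * (1 - pbar)
    if denom == 0:
        raise ValueError("single-class labels: scaled Brier undefined")
    brier = float(np.mean((scores - labels) ** 2))
    return 1.0 - brier / denom


def continuous_fit_metrics(fit) -> tuple[float, float]:
    """(adjusted R^2, MSE) of a linear FitResult; MSE uses denominator n."""
    if fit.family != "continuous":
        raise ValueError("continuous metrics require a linear fit")
    n = fit.n_used
    p = len(fit.params) - 1  # predictors excluding intercept
    if n <= p + 1:
        raise ValueError("n too small for adjusted R^2")
    return float(fit.r_squared_adj), float(fit.mse)
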