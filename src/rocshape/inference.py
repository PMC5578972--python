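"""Standard errors, confidence intervals, and paired AUROC comparison.

The single-curve SE follows Hanley & McNeil's binormal-free approximation

    SE^2 = [ A(1-A) + (m-1)(Q1 - A^2) + (n-1)(Q2 - A^2) ] / (m n)

with Q1 = A/(2-A), Q2 = 2A^2/(1+A), m event records and n non-event
records.  For two AUROCs computed from the *same* records (raw vs
transformed predictor) the difference SE needs the correlation r between
the two estimates:

    SE(diff)^2 = SE_a^2 + SE_b^2 - 2 r SE_a SE_b.

Rather than reading r from a printed table, the default method estimates it
continuously from placement values (each record's rank-based score against
the opposite class, the quantity underlying DeLong's covariance): r is the
average of the Pearson correlations of the event-side and non-event-side
placements between the two scorings.  A full DeLong variance and a paired
(stratified) bootstrap are available as alternatives.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateCIWarning, InputError, RocshapeWarning
from .roc_core import auroc_mann_whitney
from .sample import BinaryOutcomeSample, Direction

__all__ = [
    "AurocEstimate",
    "AurocComparison",
    "hanley_mcneil_se",
    "auroc_estimate",
    "compare_paired_aurocs",
    "placement_values",
]

_METHODS = ("hanley_mcneil", "delong", "bootstrap")


@dataclass(frozen=True)
class AurocEstimate:
    """AUROC with Hanley-McNeil SE and a Wald interval clipped to [0, 1]."""

    auroc: float
    se: float
    ci_low: float
    ci_high: float
    n_pos: int
    n_neg: int
    alpha: float


@dataclass(frozen=True)
class AurocComparison:
    """Paired difference between two AUROCs sharing the same records.

    ``diff`` is ``auroc_b - auroc_a``; ``r`` is the estimated correlation
    between the two AUROC estimates; ``p`` is two-sided normal.
    """

    auroc_a: float
    auroc_b: float
    diff: float
    se_diff: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    r: float
    method: str


def hanley_mcneil_se(auroc: float, n_pos: int, n_neg: int) -> float:
    """Hanley-McNeil standard error of a single AUROC.

    Zero exactly when ``auroc`` is 0 or 1.  Satisfies the class-relabelling
    identity SE(A, m, n) == SE(1 - A, n, m).
    """
    a = float(auroc)
    if not 0.0 <= a <= 1.0:
        raise InputError(f"auroc must lie in [0, 1], got {a}")
    if n_pos < 1 or n_neg < 1:
        raise InputError("n_pos and n_neg must both be >= 1")
    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    var = (
        a * (1.0 - a)
        + (n_pos - 1) * (q1 - a * a)
        + (n_neg - 1) * (q2 - a * a)
    ) / (n_pos * n_neg)
    return float(np.sqrt(max(var, 0.0)))


def auroc_estimate(
    sample: BinaryOutcomeSample,
    direction: Direction,
    alpha: float = 0.05,
) -> AurocEstimate:
    """Point estimate, Hanley-McNeil SE and Wald CI for one predictor."""
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    a = auroc_mann_whitney(sample, direction)
    m, n = sample.n_pos, sample.n_neg
    se = hanley_mcneil_se(a, m, n)
    if se == 0.0:
        warnings.warn(
            "AUROC is 0 or 1: Hanley-McNeil SE is zero and the Wald interval "
            "degenerates; consider a bootstrap interval",
            DegenerateCIWarning,
            stacklevel=2,
        )
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    lo = max(0.0, a - zq * se)
    hi = min(1.0, a + zq * se)
    return AurocEstimate(
        auroc=a, se=se, ci_low=lo, ci_high=hi, n_pos=m, n_neg=n, alpha=alpha
    )


def placement_values(
    values: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-record placement values (oriented scores assumed).

    For each event record: the fraction of non-event records scoring below
    it (ties half-weighted) — and symmetrically for non-event records.
    Both vectors average to the Mann-Whitney AUROC.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels)
    pos = v[y == 1]
    neg = v[y == 0]
    m, n = len(pos), len(neg)
    neg_sorted = np.sort(neg)
    lo = np.searchsorted(neg_sorted, pos, side="left")
    hi = np.searchsorted(neg_sorted, pos, side="right")
    v10 = (lo + 0.5 * (hi - lo)) / n
    pos_sorted = np.sort(pos)
    lo_p = np.searchsorted(pos_sorted, neg, side="left")
    hi_p = np.searchsorted(pos_sorted, neg, side="right")
    v01 = ((m - hi_p) + 0.5 * (hi_p - lo_p)) / m
    return v10, v01


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or np.std(a) == 0.0 or np.std(b) == 0.0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def compare_paired_aurocs(
    values_a: np.ndarray,
    values_b: np.ndarray,
    labels: np.ndarray,
    direction_a: Direction = Direction.HIGHER_PREDICTS_EVENT,
    direction_b: Direction = Direction.HIGHER_PREDICTS_EVENT,
    method: str = "hanley_mcneil",
    alpha: float = 0.05,
    n_boot: int = 2000,
    seed: int | None = None,
) -> AurocComparison:
    """Test the difference between two AUROCs computed on the same records.

    ``values_a`` and ``values_b`` are two scorings (e.g. raw and centered
    predictor) of the *same* records, so the estimates are correlated and
    the paired design must be honoured.

    Methods
    -------
    ``hanley_mcneil``
        Hanley-McNeil SEs with r estimated from placement-value
        correlations (default).
    ``delong``
        Full DeLong placement-based variances and covariance.
    ``bootstrap``
        Stratified paired bootstrap of the records (``n_boot`` replicates,
        ``seed`` controls the resampling).
    """
    if method not in _METHODS:
        raise InputError(f"unknown method {method!r}; expected one of {_METHODS}")
    if not 0.0 < alpha < 1.0:
        raise InputError(f"alpha must lie in (0, 1), got {alpha}")
    va = np.asarray(values_a, dtype=float)
    vb = np.asarray(values_b, dtype=float)
    y = np.asarray(labels)
    if not (len(va) == len(vb) == len(y)):
        raise InputError(
            f"length mismatch: values_a={len(va)}, values_b={len(vb)}, labels={len(y)}"
        )
    sample_a = BinaryOutcomeSample(va, y)
    sample_b = BinaryOutcomeSample(vb, y)
    sample_a.require_both_classes()
    m, n = sample_a.n_pos, sample_a.n_neg

    a_est = auroc_mann_whitney(sample_a, direction_a)
    b_est = auroc_mann_whitney(sample_b, direction_b)
    diff = b_est - a_est

    oa = direction_a.orient(va)
    ob = direction_b.orient(vb)
    v10_a, v01_a = placement_values(oa, y)
    v10_b, v01_b = placement_values(ob, y)

    if method == "bootstrap":
        rng = np.random.default_rng(seed)
        pos_idx = np.flatnonzero(y == 1)
        neg_idx = np.flatnonzero(y == 0)
        diffs = np.empty(n_boot)
        aa = np.empty(n_boot)
        bb = np.empty(n_boot)
        for k in range(n_boot):
            take = np.r_[
                rng.choice(pos_idx, size=m, replace=True),
                rng.choice(neg_idx, size=n, replace=True),
            ]
            sa = BinaryOutcomeSample(va[take], y[take])
            sb = BinaryOutcomeSample(vb[take], y[take])
            aa[k] = auroc_mann_whitney(sa, direction_a)
            bb[k] = auroc_mann_whitney(sb, direction_b)
            diffs[k] = bb[k] - aa[k]
        se_diff = float(np.std(diffs, ddof=1))
        r = _safe_corr(aa, bb)
    elif method == "delong":
        var_a = np.var(v10_a, ddof=1) / m + np.var(v01_a, ddof=1) / n
        var_b = np.var(v10_b, ddof=1) / m + np.var(v01_b, ddof=1) / n
        cov = (
            np.cov(v10_a, v10_b, ddof=1)[0, 1] / m
            + np.cov(v01_a, v01_b, ddof=1)[0, 1] / n
        )
        se_diff = float(np.sqrt(max(var_a + var_b - 2.0 * cov, 0.0)))
        denom = np.sqrt(var_a * var_b)
        r = float(cov / denom) if denom > 0 else 0.0
    else:  # hanley_mcneil with placement-correlation r
        se_a = hanley_mcneil_se(a_est, m, n)
        se_b = hanley_mcneil_se(b_est, m, n)
        r = 0.5 * (_safe_corr(v10_a, v10_b) + _safe_corr(v01_a, v01_b))
        se_diff = float(
            np.sqrt(max(se_a**2 + se_b**2 - 2.0 * r * se_a * se_b, 0.0))
        )
    r = float(np.clip(r, -1.0, 1.0))

    if diff == 0.0:
        z, p = 0.0, 1.0
    elif se_diff == 0.0:
        warnings.warn(
            "zero SE for a non-zero AUROC difference; reporting p = 0",
            RocshapeWarning,
            stacklevel=2,
        )
        z = np.inf if diff > 0 else -np.inf
        p = 0.0
    else:
        z = diff / se_diff
        p = float(2.0 * stats.norm.sf(abs(z)))
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    return AurocComparison(
        auroc_a=a_est,
        auroc_b=b_est,
        diff=diff,
        se_diff=se_diff,
        ci_low=diff - zq * se_diff,
        ci_high=diff + zq * se_diff,
        z=float(z),
        p=float(p),
        r=r,
        method=method,
    )
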