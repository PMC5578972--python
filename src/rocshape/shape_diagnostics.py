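"""Diagnostics for non-standard ROC shapes.

A proper ROC curve of a monotone-risk predictor is concave-downward and
stays on or above the chance diagonal.  Non-monotone risk bends the curve
through the diagonal:

* a **U-shaped** predictor ranks one event-rich extreme first, so the curve
  climbs above the diagonal early, goes flat through the event-poor middle,
  and dips below before the second event-rich extreme pulls it back to
  (1, 1) — the steep/flat/steep *logit* (inverse-sigmoidal) shape;
* an **inverted-U** predictor does the opposite: flat/steep/flat, below the
  diagonal first — the *sigmoidal* shape.

Either way the curve crosses the diagonal at an interior point; at that
operating point TPR == FPR, so both cumulative likelihood ratios equal one
and the corresponding threshold carries no predictive value.  The crossing
maps back to the nadir (or peak) of the risk relation.

Classification is tolerance-based: empirical staircases wobble around the
diagonal, so only excursions beyond ``tolerance`` (default 0.02, in
TPR - FPR units) count as being off the diagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InputError
from .roc_core import ROCCurve

__all__ = [
    "ShapeReport",
    "diagonal_crossings",
    "classify_shape",
    "likelihood_ratios",
    "DEFAULT_TOLERANCE",
]

DEFAULT_TOLERANCE = 0.02

SHAPE_LABELS = (
    "proper_concave",
    "inverse_sigmoidal",
    "sigmoidal",
    "near_diagonal",
    "irregular",
)


@dataclass(frozen=True)
class ShapeReport:
    """Result of :func:`classify_shape`.

    ``crossings`` are interior diagonal crossings as (fpr, tpr) pairs with
    fpr == tpr; excursions are the largest signed distances tpr - fpr above
    and below the diagonal (both reported as non-negative magnitudes).
    """

    label: str
    crossings: tuple[tuple[float, float], ...]
    max_excursion_above: float
    max_excursion_below: float
    tolerance: float


def _significant_bands(e: np.ndarray, tolerance: float) -> list[tuple[int, int, int]]:
    """Maximal vertex runs where the excursion exceeds the tolerance.

    Returns (sign, first_vertex, last_vertex) triples in curve order.
    """
    sig = np.zeros(len(e), dtype=int)
    sig[e > tolerance] = 1
    sig[e < -tolerance] = -1
    bands: list[tuple[int, int, int]] = []
    for i, s in enumerate(sig):
        if s == 0:
            continue
        if bands and bands[-1][0] == s:
            bands[-1] = (s, bands[-1][1], i)
        else:
            bands.append((s, i, i))
    return bands


def _zero_candidates(curve: ROCCurve, lo: int, hi: int) -> list[float]:
    """Interpolated diagonal touch points within vertex range [lo, hi]."""
    f, t = curve.fpr, curve.tpr
    e = t - f
    out: list[float] = []
    i = lo
    while i < hi:
        if e[i] == 0.0:
            # run of exactly-on-diagonal vertices: report the run midpoint once
            j = i
            while j + 1 <= hi and e[j + 1] == 0.0:
                j += 1
            out.append(float((f[i] + f[j]) / 2.0))
            i = j + 1
            continue
        if e[i] * e[i + 1] < 0.0:
            w = e[i] / (e[i] - e[i + 1])
            out.append(float(f[i] + w * (f[i + 1] - f[i])))
        i += 1
    if i == hi and e[hi] == 0.0:
        out.append(float(f[hi]))
    return out


def diagonal_crossings(
    curve: ROCCurve, tolerance: float = DEFAULT_TOLERANCE
) -> list[tuple[float, float]]:
    """Interior points where the curve crosses the chance diagonal.

    A crossing is reported only between excursions exceeding ``tolerance``
    on *both* sides (macroscopic crossings, not staircase wobble); its
    location comes from linear interpolation within the crossing segment.
    If several micro-crossings separate the two significant regions, the
    middle one is reported — deterministic and order-independent.  Crossings
    within ``tolerance`` of the (0,0) / (1,1) corners are discarded.
    """
    if tolerance <= 0:
        raise InputError("tolerance must be positive")
    e = curve.tpr - curve.fpr
    bands = _significant_bands(e, tolerance)
    crossings: list[tuple[float, float]] = []
    for prev, nxt in zip(bands, bands[1:]):
        if prev[0] == nxt[0]:  # pragma: no cover - bands are sign-alternating
            continue
        cands = _zero_candidates(curve, prev[2], nxt[1])
        if not cands:  # pragma: no cover - continuity guarantees one
            continue
        u = sorted(cands)[len(cands) // 2]
        if tolerance < u < 1.0 - tolerance:
            crossings.append((u, u))
    return crossings


def classify_shape(
    curve: ROCCurve, tolerance: float = DEFAULT_TOLERANCE
) -> ShapeReport:
    """Classify the macroscopic shape of an ROC curve.

    Labels:

    * ``near_diagonal`` — never further than ``tolerance`` from chance;
    * ``proper_concave`` — meaningfully above the diagonal, never
      meaningfully below (the textbook shape);
    * ``inverse_sigmoidal`` — one interior crossing, above-diagonal region
      first (U-shaped risk);
    * ``sigmoidal`` — one interior crossing, below-diagonal region first
      (inverted-U risk);
    * ``irregular`` — anything else (two or more crossings, or entirely
      below the diagonal).
    """
    e = curve.tpr - curve.fpr
    max_above = float(max(e.max(), 0.0))
    max_below = float(max(-e.min(), 0.0))
    crossings = tuple(diagonal_crossings(curve, tolerance))
    bands = _significant_bands(e, tolerance)

    if max_above <= tolerance and max_below <= tolerance:
        label = "near_diagonal"
    elif max_below <= tolerance:
        label = "proper_concave"
    elif len(crossings) == 1 and len(bands) == 2:
        label = "inverse_sigmoidal" if bands[0][0] > 0 else "sigmoidal"
    else:
        label = "irregular"
    return ShapeReport(
        label=label,
        crossings=crossings,
        max_excursion_above=max_above,
        max_excursion_below=max_below,
        tolerance=tolerance,
    )


def likelihood_ratios(curve: ROCCurve) -> pd.DataFrame:
    """Cumulative and interval likelihood ratios along the curve.

    Per ROC point: ``cum_lr_pos`` = TPR/FPR (slope of the chord from (0,0)),
    ``cum_lr_neg`` = (1-TPR)/(1-FPR) (chord from (1,1)), and ``interval_lr``
    = slope of the staircase segment ending at that point — the likelihood
    ratio of a result falling in that threshold interval.

    Undefined ratios (0/0 corners, first point's interval) are NaN; a
    vertical segment's interval LR is +inf.  At any diagonal crossing both
    cumulative LRs equal one.
    """
    f, t = curve.fpr, curve.tpr

    with np.errstate(divide="ignore", invalid="ignore"):
        lr_pos = np.where(f > 0, t / np.where(f > 0, f, 1.0), np.nan)
        lr_pos = np.where((f == 0) & (t > 0), np.inf, lr_pos)
        lr_neg = np.where(f < 1, (1 - t) / np.where(f < 1, 1 - f, 1.0), np.nan)
        lr_neg = np.where((f == 1) & (t < 1), np.inf, lr_neg)

    df = np.diff(f)
    dt = np.diff(t)
    with np.errstate(divide="ignore", invalid="ignore"):
        seg = np.where(df > 0, dt / np.where(df > 0, df, 1.0), np.inf)
        seg = np.where((df == 0) & (dt == 0), np.nan, seg)
    interval = np.r_[np.nan, seg]

    return pd.DataFrame(
        {
            "threshold": curve.thresholds,
            "fpr": f,
            "tpr": t,
            "cum_lr_pos": lr_pos,
            "cum_lr_neg": lr_neg,
            "interval_lr": interval,
        }
    )
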