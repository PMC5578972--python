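"""Predictor transformations that rescue non-monotone risk relationships.

A predictor whose outcome risk is U-shaped (high at both extremes, minimal
at a central nadir) discriminates poorly on its raw scale: concordance from
the two arms cancels and AUROC shrinks toward 0.5.  *Centering* — replacing
x with its squared distance (x - c)^2 from a chosen center c — converts the
U into an approximately monotone relation and restores discrimination.
Strictly monotone transforms (log, square on positive data) cannot do this:
they leave the ranking, and hence the AUROC, untouched.

Available kinds:

========================  ====================================
``identity``              x
``center_square``         (x - c)^2
``log``                   ln x        (requires x > 0)
``square``                x^2
``negate``                -x
``fold``                  |x - c|     (nadir folding)
========================  ====================================

``fold`` and ``center_square`` are monotone-related (t -> t^2 on t >= 0),
so they always yield identical AUROCs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError, NadirWarning
from .sample import BinaryOutcomeSample

__all__ = [
    "TransformSpec",
    "apply_transform",
    "center_from_sample",
    "estimate_nadir",
]

_KINDS = ("identity", "center_square", "log", "square", "negate", "fold")
_NEEDS_CENTER = ("center_square", "fold")


@dataclass(frozen=True)
class TransformSpec:
    """A named elementwise transform, with a center where one is required.

    ``center`` is mandatory (and must be finite) for ``center_square`` and
    ``fold``; it is ignored for the other kinds.
    """

    kind: str
    center: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ConfigurationError(
                f"unknown transform kind {self.kind!r}; expected one of {_KINDS}"
            )
        if self.kind in _NEEDS_CENTER:
            if self.center is None or not np.isfinite(self.center):
                raise ConfigurationError(
                    f"transform {self.kind!r} requires a finite center"
                )

    def describe(self) -> str:
        if self.kind in _NEEDS_CENTER:
            return f"{self.kind}:{self.center:g}"
        return self.kind


def apply_transform(values: np.ndarray, spec: TransformSpec) -> np.ndarray:
    """Apply ``spec`` elementwise; output has the same length as the input."""
    x = np.asarray(values, dtype=float)
    if spec.kind == "identity":
        return x.copy()
    if spec.kind == "center_square":
        return (x - spec.center) ** 2
    if spec.kind == "fold":
        return np.abs(x - spec.center)
    if spec.kind == "square":
        return x**2
    if spec.kind == "negate":
        return -x
    if spec.kind == "log":
        bad = np.flatnonzero(x <= 0)
        if bad.size:
            raise InputError(
                f"log transform requires positive values; offending index {int(bad[0])}"
                f" (value {x[bad[0]]!r})"
            )
        return np.log(x)
    raise ConfigurationError(f"unknown transform kind {spec.kind!r}")  # pragma: no cover


def center_from_sample(values: np.ndarray, statistic: str = "median") -> float:
    """Arithmetic mean or sample median of the values.

    The median of an even-length sample is the average of the two middle
    order statistics.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise InputError("cannot compute a center from an empty vector")
    if not np.all(np.isfinite(x)):
        raise InputError("center_from_sample requires finite values")
    if statistic == "mean":
        return float(np.mean(x))
    if statistic == "median":
        return float(np.median(x))
    raise ConfigurationError(
        f"unknown centering statistic {statistic!r}; expected 'mean' or 'median'"
    )


def estimate_nadir(sample: BinaryOutcomeSample, n_bins: int = 20) -> float:
    """Estimate the risk nadir: the predictor value of minimum event rate.

    Values are split into ``n_bins`` equal-count (quantile) bins — robust to
    skewed predictors — and the midpoint of the bin with the lowest event
    rate is returned, breaking exact rate ties toward the bin nearest the
    sample median.

    Emits :class:`~rocshape.errors.NadirWarning` when the minimum sits in an
    extreme bin (risk may be monotone, not U-shaped) or when the bin rates
    are too flat to identify a minimum (max - min rate below twice the
    pooled binomial SE of those two bins).
    """
    from .simulate import estimate_risk_curve  # local import: no cycle back

    if n_bins < 3:
        raise ConfigurationError("estimate_nadir needs n_bins >= 3")
    sample.require_both_classes()
    curve = estimate_risk_curve(sample, n_bins)
    rates = curve.event_rate
    mids = curve.bin_midpoints
    counts = curve.bin_counts

    med = float(np.median(sample.values))
    min_rate = rates.min()
    candidates = np.flatnonzero(rates == min_rate)
    best = int(candidates[np.argmin(np.abs(mids[candidates] - med))])

    i_max = int(np.argmax(rates))
    p_pool = (rates[best] * counts[best] + rates[i_max] * counts[i_max]) / (
        counts[best] + counts[i_max]
    )
    pooled_se = np.sqrt(
        max(p_pool * (1 - p_pool), 1e-12) * (1 / counts[best] + 1 / counts[i_max])
    )
    if rates[i_max] - rates[best] < 2 * pooled_se:
        warnings.warn(
            "nadir not identifiable: bin event rates are flat relative to "
            "their binomial noise",
            NadirWarning,
            stacklevel=2,
        )
    elif best in (0, len(rates) - 1):
        warnings.warn(
            "minimum event rate falls in an extreme bin; the risk relation "
            "may be monotone rather than U-shaped",
            NadirWarning,
            stacklevel=2,
        )
    return float(mids[best])
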