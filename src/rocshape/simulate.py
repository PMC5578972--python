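"""Seeded generator of binary-outcome data with controllable risk shapes.

The generative model draws a continuous predictor x from a chosen
distribution and an outcome label from a Bernoulli whose probability is a
logistic function of x:

* ``u``           logit p(x) = b0 + s(x) (x - c)^2   — risk minimal at the
  nadir c, rising on both sides with separately tunable arm steepnesses
  (``steep_left`` applies for x < c, ``steep_right`` for x >= c);
* ``inverted_u``  logit p(x) = b0 - s(x) (x - c)^2   — risk peaks at c;
* ``monotone``    logit p(x) = b0 + slope * x;
* ``flat``        logit p(x) = b0.

``b0`` is the log-odds of the event at the center (or everywhere, for
``flat``).  Identical (model, n, seed) triples give bit-identical samples.

Presets
-------
``ph_like``
    Emulates a critical-care arterial-pH cohort: a left-skewed predictor
    (skew-normal, calibrated so a large sample has mean ~7.34, median
    ~7.36, IQR ~[7.28, 7.41]; see ``scripts/calibrate_ph_like.py``) with an
    asymmetric U — the acidotic arm steeper than the alkalotic arm and the
    nadir at the median.  Event rate ~0.17.
``inverted_u_500``
    A symmetric inverted-U over a standard-normal predictor, sized for
    n = 500: risk peaks at the center and vanishes in both tails, the
    configuration that produces a sigmoidal ROC.
``monotone_demo``
    Ordinary monotone log-odds risk: the textbook proper-concave ROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import expit

from .errors import ConfigurationError, InputError, RocshapeWarning
from .sample import BinaryOutcomeSample

__all__ = [
    "RiskModelSpec",
    "RiskCurveEstimate",
    "simulate_dataset",
    "preset_model",
    "estimate_risk_curve",
    "PH_LIKE_SKEWNORM",
]

_DISTS = ("normal", "lognormal", "skew_normal")
_SHAPES = ("u", "inverted_u", "monotone", "flat")

# Skew-normal (shape, location, scale): location/scale fitted by least
# squares to mean 7.34, median 7.36, quartiles [7.28, 7.41] at fixed shape
# -3; the moderate skew keeps real mass in the alkalotic (right) tail, which
# stronger skews suppress entirely.  Frozen here, reproducible via
# scripts/calibrate_ph_like.py.
PH_LIKE_SKEWNORM = (-3.0, 7.4556, 0.1510)


@dataclass(frozen=True)
class RiskModelSpec:
    """Generative description of a predictor distribution plus risk shape."""

    predictor_dist: str = "normal"
    location: float = 0.0
    scale: float = 1.0
    shape: float = 0.0  # skew parameter, used by skew_normal only
    risk_shape: str = "u"
    center: float = 0.0  # nadir (u) or peak (inverted_u)
    steep_left: float = 1.0
    steep_right: float = 1.0
    baseline: float = 0.0  # log-odds at the center
    monotone_slope: float = 1.0  # used by risk_shape == "monotone" only

    def __post_init__(self) -> None:
        if self.predictor_dist not in _DISTS:
            raise ConfigurationError(
                f"unknown predictor_dist {self.predictor_dist!r}; one of {_DISTS}"
            )
        if self.risk_shape not in _SHAPES:
            raise ConfigurationError(
                f"unknown risk_shape {self.risk_shape!r}; one of {_SHAPES}"
            )
        if self.scale <= 0:
            raise ConfigurationError("scale must be positive")
        if self.steep_left < 0 or self.steep_right < 0:
            raise ConfigurationError("steepness parameters must be non-negative")
        for name in ("location", "center", "baseline", "monotone_slope", "shape"):
            if not np.isfinite(getattr(self, name)):
                raise ConfigurationError(f"{name} must be finite")

    def event_probability(self, x: np.ndarray) -> np.ndarray:
        """p(event | x) under the model; always strictly inside (0, 1)."""
        x = np.asarray(x, dtype=float)
        if self.risk_shape == "flat":
            logit = np.full_like(x, self.baseline)
        elif self.risk_shape == "monotone":
            logit = self.baseline + self.monotone_slope * x
        else:
            s = np.where(x < self.center, self.steep_left, self.steep_right)
            bump = s * (x - self.center) ** 2
            sign = 1.0 if self.risk_shape == "u" else -1.0
            logit = self.baseline + sign * bump
        return expit(logit)

    def draw_predictor(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if self.predictor_dist == "normal":
            return rng.normal(self.location, self.scale, size=n)
        if self.predictor_dist == "lognormal":
            return rng.lognormal(self.location, self.scale, size=n)
        return stats.skewnorm.rvs(
            self.shape, loc=self.location, scale=self.scale, size=n, random_state=rng
        )


@dataclass(frozen=True)
class RiskCurveEstimate:
    """Binned empirical risk curve: event rate per equal-count predictor bin."""

    bin_edges: np.ndarray
    bin_midpoints: np.ndarray
    event_rate: np.ndarray
    bin_counts: np.ndarray


def simulate_dataset(
    model: RiskModelSpec, n: int, seed: int
) -> BinaryOutcomeSample:
    """Draw a seeded sample of (predictor, outcome) pairs from ``model``."""
    if n < 2:
        raise InputError(f"need n >= 2, got {n}")
    rng = np.random.default_rng(seed)
    x = model.draw_predictor(n, rng)
    p = model.event_probability(x)
    y = (rng.random(n) < p).astype(np.int8)
    return BinaryOutcomeSample(x, y)


def preset_model(name: str) -> RiskModelSpec:
    """Return one of the shipped study presets (see module docstring)."""
    if name == "ph_like":
        a, loc, scale = PH_LIKE_SKEWNORM
        return RiskModelSpec(
            predictor_dist="skew_normal",
            shape=a,
            location=loc,
            scale=scale,
            risk_shape="u",
            center=7.36,
            steep_left=180.0,
            steep_right=170.0,
            baseline=-3.3,
        )
    if name == "inverted_u_500":
        return RiskModelSpec(
            predictor_dist="normal",
            location=0.0,
            scale=1.0,
            risk_shape="inverted_u",
            center=0.0,
            steep_left=4.0,
            steep_right=4.0,
            baseline=1.0,
        )
    if name == "monotone_demo":
        return RiskModelSpec(
            predictor_dist="normal",
            location=0.0,
            scale=1.0,
            risk_shape="monotone",
            baseline=-1.5,
            monotone_slope=1.5,
        )
    raise ConfigurationError(
        f"unknown preset {name!r}; expected ph_like, inverted_u_500 or monotone_demo"
    )


def symmetric_u_model(
    steepness: float = 4.0, baseline: float = -2.0
) -> RiskModelSpec:
    """Standard-normal predictor with a symmetric U centered at zero.

    The canonical null-bias configuration: raw AUROC converges to 0.5 as n
    grows while squared-distance centering at zero restores discrimination.
    """
    return RiskModelSpec(
        predictor_dist="normal",
        risk_shape="u",
        center=0.0,
        steep_left=steepness,
        steep_right=steepness,
        baseline=baseline,
    )


def estimate_risk_curve(
    sample: BinaryOutcomeSample, n_bins: int
) -> RiskCurveEstimate:
    """Empirical risk curve: event rate in equal-count predictor bins.

    Bins with fewer than 5 records are merged into their left neighbour
    (the first bin merges right).  If the data have too few distinct values
    for ``n_bins`` quantile edges, the bin count is reduced with a warning.
    """
    if n_bins < 2:
        raise InputError("need n_bins >= 2")
    x = sample.values
    y = sample.labels

    edges = np.quantile(x, np.linspace(0.0, 1.0, n_bins + 1))
    edges = np.unique(edges)
    if len(edges) - 1 < n_bins:
        warnings.warn(
            f"only {len(edges) - 1} distinct quantile bins available "
            f"(requested {n_bins})",
            RocshapeWarning,
            stacklevel=2,
        )
    if len(edges) < 3:
        edges = np.array([x.min(), np.median(x), x.max()], dtype=float)
        edges = np.unique(edges)
    # right-closed last bin so the maximum lands in the final bin
    idx = np.clip(np.searchsorted(edges, x, side="right") - 1, 0, len(edges) - 2)

    groups: list[list[int]] = [[b] for b in range(len(edges) - 1)]
    counts = np.bincount(idx, minlength=len(edges) - 1)

    def group_count(g: list[int]) -> int:
        return int(sum(counts[b] for b in g))

    k = 0
    while k < len(groups):
        if group_count(groups[k]) < 5 and len(groups) > 1:
            if k == 0:
                groups[1] = groups[0] + groups[1]
                groups.pop(0)
            else:
                groups[k - 1] = groups[k - 1] + groups[k]
                groups.pop(k)
                k -= 1
        else:
            k += 1

    lo_edges, hi_edges, rates, gcounts = [], [], [], []
    for g in groups:
        members = np.isin(idx, g)
        cnt = int(members.sum())
        lo_edges.append(edges[min(g)])
        hi_edges.append(edges[max(g) + 1])
        rates.append(float(y[members].mean()) if cnt else np.nan)
        gcounts.append(cnt)
    final_edges = np.array(lo_edges + [hi_edges[-1]], dtype=float)
    mids = (final_edges[:-1] + final_edges[1:]) / 2.0
    return RiskCurveEstimate(
        bin_edges=final_edges,
        bin_midpoints=mids,
        event_rate=np.array(rates),
        bin_counts=np.array(gcounts),
    )
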