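# Methods

This note documents the statistical content of `rocshape`: the estimators,
the generative models behind the simulator, the numerical conventions, and
what the test suite does and does not establish about real data.

## The problem

The AUROC of a continuous predictor equals the probability that a randomly
chosen event record outranks a randomly chosen non-event record. That
interpretation — and the usefulness of the number — presumes the risk of
the outcome is monotone in the predictor. When risk is **U-shaped**
(high at both extremes, minimal at a nadir c), the two arms of the U
generate concordance of opposite sign. In the pairwise sum these
contributions cancel, pushing the AUROC toward 0.5 regardless of how
informative the predictor actually is ("null bias"). The cancellation is a
property of the ranking itself, so no strictly monotone transform (log,
squaring a positive predictor) can repair it; only a transform that folds
the two arms onto one scale can. The geometric signature is equally
diagnostic: ranking by a U-shaped predictor puts one event-rich extreme
first and the other last, so the empirical ROC rises above the chance
diagonal early and dips below it before the (1,1) corner — a
steep/flat/steep, logit-like ("inverse-sigmoidal") curve with one interior
diagonal crossing. An inverted-U predictor produces the mirror-image
flat/steep/flat ("sigmoidal") curve. At any interior crossing TPR = FPR,
hence cumulative LR(+) = TPR/FPR = 1 and LR(−) = (1−TPR)/(1−FPR) = 1: the
threshold generating that operating point is predictively worthless, and
it maps back to the nadir (or peak) of the risk relation.

## Estimators

**AUROC.** `auroc_mann_whitney` computes the pairwise score mean — 1 for a
win, 0.5 for an exact tie, 0 for a loss — via average ranks in O(N log N).
The half-credit tie rule is what makes the pairwise statistic equal the
trapezoidal area under the empirical staircase (`auroc_trapezoid`); the
suite asserts agreement to 1e-12 against an exact rational brute-force
oracle. One numerical refinement: the final division always uses the
smaller of the two complementary numerators, which makes
AUROC(higher) + AUROC(lower) equal 1.0 *bitwise* rather than to within a
rounding error.

**ROC construction.** Thresholds sweep the distinct observed values on the
oriented scale ("value ≥ threshold calls positive"); ties collapse to a
single vertex; a +inf sentinel supplies the (0,0) corner. Under
`lower_predicts_event` the values are negated before thresholding, so
reported thresholds live on the oriented (negated) scale.

**Hanley–McNeil SE.** SE² = [A(1−A) + (m−1)(Q₁−A²) + (n−1)(Q₂−A²)]/(mn)
with Q₁ = A/(2−A), Q₂ = 2A²/(1+A). It is zero exactly at A ∈ {0,1} (a
warning recommends the bootstrap there) and satisfies the class-relabelling
identity SE(A,m,n) = SE(1−A,n,m). Wald intervals are clipped to [0,1].

**Paired comparison.** Two scorings of the same records are correlated;
SE(diff)² = SE_a² + SE_b² − 2 r SE_a SE_b. The classical presentation of
this method reads r from a printed table; we instead estimate r
continuously from **placement values** (each record's rank-based score
against the opposite class — the quantity that underlies the DeLong
covariance): r is the average of the event-side and non-event-side
placement correlations. This is the default (`hanley_mcneil`). Two
alternatives are provided: `delong` (full placement variances and
covariance, no Hanley–McNeil approximation) and `bootstrap` (stratified
paired resampling of records, preserving class sizes). p-values are
two-sided normal throughout; a zero SE with a non-zero difference is
reported as p = 0 with a warning. Empirically (asserted in the suite) the
default method's type-I error over 1000 null replicates at n = 200 lies in
[0.03, 0.07] at α = 0.05, its SE is within 15% of a 2000-replicate
bootstrap, and its z agrees with DeLong's within 10% on large samples.

## Transforms

`center_square` (x−c)², `fold` |x−c| (identical rankings, asserted equal
AUROC), `log`, `square`, `negate`, `identity`. The center may be supplied,
taken as the sample mean or median (even-length median = mean of the middle
pair), or estimated. `estimate_nadir` bins the predictor into equal-count
(quantile) bins — robust to skewed predictors — and returns the midpoint of
the minimum-event-rate bin, breaking ties toward the bin nearest the
median. It warns when the minimum lands in an extreme bin (risk may be
monotone) and when the bin-rate range is under twice the pooled binomial SE
of the extreme bins (nadir not identifiable). The fold is symmetric; an
asymmetric two-sided rescaling (treating sub-nadir values as equivalent to
specific supra-nadir values) would need the true shape of both risk arms
and is out of scope.

## Shape classification

Signed excursion e = TPR − FPR along the piecewise-linear curve (linear in
the segment parameter, so vertex extremes suffice). Only excursions beyond
a tolerance (default **0.02**) count: empirical staircases wobble around
the diagonal, and the shapes of interest are macroscopic. Rules:

* `near_diagonal` — |e| ≤ tol everywhere;
* `proper_concave` — meaningfully above, never meaningfully below;
* `inverse_sigmoidal` — exactly one significant crossing, above-region
  first (U-shaped risk);
* `sigmoidal` — one significant crossing, below-region first (inverted-U);
* `irregular` — anything else (≥ 2 crossings, or entirely below).

Crossings are located by linear interpolation inside the crossing segment;
when several micro-crossings separate two significant regions the middle
one is reported (deterministic); an exactly-on-diagonal run reports its
midpoint once; crossings within the tolerance of the corners are
discarded. Note that flipping the predictor's direction rotates the curve
180° about (½,½), which preserves the excursion-sign sequence and hence
the class; the operation that exchanges sigmoidal and inverse-sigmoidal is
the mirror (FPR,TPR) → (TPR,FPR), i.e. relabelling the outcome classes.
Both facts are asserted in the suite.

## The simulator

Risk is logistic in squared distance from a center:
logit p(x) = b0 + s(x)(x−c)² for U-shaped risk (s = steep_left left of c,
steep_right right of c), the negated bump for inverted-U, b0 + slope·x for
monotone, b0 for flat. b0 is the log-odds at the center. The logistic-
quadratic link is the simplest smooth two-armed form with independently
controllable arms; it is a modelling choice, not an estimate of any real
cohort's risk function. Identical (model, n, seed) triples are
bit-reproducible (`numpy` Generator, single seed).

**`ph_like`** emulates the statistical structure of a critical-care
arterial-pH cohort: a left-skewed skew-normal predictor
(shape −3, location 7.4556, scale 0.1510 — fitted once by least squares so
that mean ≈ 7.34, median ≈ 7.36, IQR ≈ [7.28, 7.41]; constants frozen,
`scripts/calibrate_ph_like.py` reproduces them) with an asymmetric U:
nadir 7.36, steep_left 180 > steep_right 170 (the acidosis arm steeper),
baseline log-odds −3.3, event rate ≈ 0.21. The skew is fixed at −3 rather
than fitted freely: a freer fit matches the quartile asymmetry marginally
better but strips the alkalotic tail of mass, and a U-shaped risk model
needs both arms populated. With these defaults the preset reproduces the
qualitative phenomenology of such a cohort: raw AUROC
(lower-predicts-event) ≈ 0.71 < mean-centered ≈ 0.88 < median-centered
≈ 0.89, an inverse-sigmoidal raw curve, proper-concave centered curves,
and median-centering beating mean-centering because the left-skewed
median sits nearer the nadir. **`inverted_u_500`** is a symmetric
inverted-U over N(0,1) (peak risk logistic(1) at the center, steepness 4),
sized for n = 500 but robust at larger n. **`monotone_demo`** is ordinary
monotone log-odds risk. `symmetric_u_model()` (N(0,1), c = 0, steepness 4,
b0 = −2) is the canonical null-bias configuration used throughout the
tests and the acceptance script.

`estimate_risk_curve` reports event rates over equal-count bins, merging
bins under 5 records leftward and reducing the bin count (with a warning)
when distinct values run short.

## What the synthetic data do and do not show

The generator emulates the *structure* reported for the motivating
clinical data — summary location/spread/skew of the predictor, asymmetric
U-shaped risk, and the resulting ROC phenomenology — not any real cohort's
numbers. Real data add features the simulator omits: measurement rounding
and heaping, covariate confounding, non-quadratic and non-logistic risk,
informative missingness. Passing tests therefore demonstrate that the
estimators and diagnostics behave correctly *when the model holds*, and
that the null-bias/centering phenomena are genuine mathematical properties
of ranking statistics; they do not certify effect sizes in any particular
clinical dataset.

## Numerical conventions and problem sizes

Ties get half credit everywhere (scores, placements). Even-length medians
average the middle pair. Wald intervals are clipped to [0,1]. Undefined
likelihood ratios (0/0) are NaN, never silent infinities; a vertical
segment's interval LR is +inf, serialized as the string "inf" (NaN as
null) in JSON/CSV output. The analysis pipeline writes reports atomically
(temp file + rename) and validates them against a lightweight structural
schema. All randomness in a pipeline run flows from one top-level seed.

The simulation-backed tests use n = 20,000 × 20 seeds for the null-bias
law, n = 5,000 × 100 seeds for shape phenomenology, n = 200 × 1,000
replicates for test calibration, and n = 20,000 × 50 seeds for nadir
recovery; these sizes put Monte-Carlo error well inside the asserted
margins while keeping the suite fast.

## Known limitations

* Parametric (binormal) ROC fitting, partial AUROC, covariate adjustment,
  weighted samples and multi-class ROC are out of scope.
* The shape labels operationalize visual descriptions; the 0.02 tolerance
  is a reasonable default for n ≳ 1000, not a universal constant. Very
  small samples mostly classify `near_diagonal` or `irregular`.
* `estimate_nadir` assumes a single minimum; bimodal risk minima are
  reported as whichever bin wins, with no multimodality diagnostic.
* Whether median-centering generically beats mean-centering depends on the
  direction of the predictor's skew relative to the risk asymmetry; the
  package asserts it only for the shipped pH-like configuration.
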