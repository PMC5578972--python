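# rocshape

ROC analysis for **non-linear (U-shaped) continuous predictors** of binary
outcomes.

Many physiological predictors — arterial pH, temperature, white-cell count,
potassium, body-mass index — have *U-shaped* risk: outcome risk is high at
both extremes and minimal at a central **nadir**. Ordinary ROC analysis
silently assumes monotone risk, and a U-shaped predictor pays for that
assumption twice:

* its **AUROC is biased toward 0.5** (the two arms of the U generate
  opposing concordance that cancels), and
* its ROC curve is no longer concave: a U-shaped predictor produces a
  logit-like **inverse-sigmoidal** curve and an inverted-U predictor a
  **sigmoidal** curve, each crossing the chance diagonal at an interior
  point where both likelihood ratios equal one.

`rocshape` is a library (plus a thin CLI) for clinicians and
epidemiologists auditing such predictors: it quantifies the bias, detects
the shape signature, and applies the centering remedy.

## The statistics

**Nonparametric AUROC.** For m event records with predictor values P_i and
n non-event records with values P_j,

    AUROC = (1/mn) Σ_i Σ_j s(P_i, P_j),    s = 1 if P_i > P_j, ½ if tied, 0 otherwise

computed via average ranks (Mann–Whitney) and, independently, as the
trapezoidal area under the empirical ROC staircase; the two agree to
machine precision. Orientation is always explicit
(`higher_predicts_event` / `lower_predicts_event`), and
AUROC(lower) = 1 − AUROC(higher) holds exactly.

**Centering.** The remedy for a U-shaped predictor x with nadir c is the
squared-distance re-scoring x ↦ (x − c)², or equivalently the fold
x ↦ |x − c| (identical AUROC: the two are monotone-related). The center
can be the sample mean, the sample median, a known value, or the estimated
nadir (`estimate_nadir`: minimum-event-rate quantile bin). Strictly
monotone transforms (log, squaring a positive predictor) provably change
nothing — the package asserts this invariance.

**Inference.** Single-curve SE by Hanley–McNeil:
SE² = [A(1−A) + (m−1)(Q₁−A²) + (n−1)(Q₂−A²)]/(mn), Q₁ = A/(2−A),
Q₂ = 2A²/(1+A). Paired comparison of two scorings of the *same* records
(raw vs centered) via SE(diff)² = SE_a² + SE_b² − 2 r SE_a SE_b with the
correlation r estimated from placement values (DeLong-style), plus full
DeLong and stratified-bootstrap alternatives.

**Shape diagnostics.** Tolerance-based classification of the empirical
curve (`proper_concave`, `inverse_sigmoidal`, `sigmoidal`,
`near_diagonal`, `irregular`), interior diagonal crossings by linear
interpolation, and cumulative/interval likelihood-ratio tables.

**Simulation.** A seeded generator with logistic risk in squared distance
from a center: logit p(x) = b0 ± s(x)(x−c)², with separately tunable arm
steepnesses, plus monotone and flat shapes. Presets: `ph_like` (left-skewed
predictor emulating a critical-care arterial-pH cohort — mean ≈ 7.34,
median ≈ 7.36, IQR ≈ 7.28–7.41 — with an asymmetric U, acidosis arm
steeper), `inverted_u_500`, and `monotone_demo`.

## Worked example

```python
import rocshape as rs

config = rs.AnalysisConfig(
    preset="ph_like", n=5000, seed=7,
    direction=rs.Direction.LOWER_PREDICTS_EVENT,   # low pH predicts death
    transforms=(
        rs.TransformRequest("center_square", "mean"),
        rs.TransformRequest("center_square", "median"),
    ),
)
report = rs.run_analysis(config)
```

Printing the key fields (`python examples/ph_cohort_audit.py`) gives:

```
n = 5000  (events: 1032)
identity               AUROC 0.714 (95% CI 0.695-0.733)  shape: inverse_sigmoidal
center_square:mean     AUROC 0.880 (95% CI 0.866-0.894)  shape: proper_concave
center_square:median   AUROC 0.890 (95% CI 0.877-0.903)  shape: proper_concave
center_square:mean     vs raw: diff +0.166 (95% CI +0.142 to +0.191), p = 1.1e-40
center_square:median   vs raw: diff +0.176 (95% CI +0.154 to +0.198), p = 8.2e-57
```

Reading: the raw pH staircase is inverse-sigmoidal (it crosses the
diagonal — part of the curve is *anti*-predictive), and its AUROC of 0.714
understates the predictor. Squared-distance centering restores the proper
concave shape and lifts the AUROC significantly; centering at the median
beats the mean because this left-skewed cohort's median lies closer to the
risk nadir.

The other scripts in `examples/` each demonstrate one capability: the
null-bias law (`null_bias.py`), shape diagnostics and diagonal crossings
(`shape_diagnostics_tour.py`), nadir estimation and folding
(`nadir_estimation.py`), and the three comparison methods
(`compare_methods.py`).

## Command line

```bash
rocshape simulate --preset ph_like --n 10000 --seed 42 --out sample.csv
rocshape roc      --input sample.csv --direction lower_predicts_event --out roc.csv
rocshape shape    --input sample.csv --lr-table lr.csv
rocshape center   --input sample.csv --by median --kind center_square --out centered.csv
rocshape compare  --input sample.csv --transform-b center_square:median \
                  --direction-a lower_predicts_event
rocshape analyze  --preset ph_like --n 5000 --seed 7 \
                  --direction lower_predicts_event --out report.json
```

Exit codes: 0 success, 2 input/configuration error, 3 degenerate data
(single outcome class).

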