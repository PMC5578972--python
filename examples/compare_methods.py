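"""Three routes to the same paired AUROC comparison.

Two scorings of the same subjects give correlated AUROC estimates; the
difference test must account for that correlation.  The Hanley-McNeil
method estimates it from placement-value correlations, the DeLong method
uses the full placement covariance, and the bootstrap resamples subjects.
"""

import numpy as np

import rocshape as rs

L, H = rs.Direction.LOWER_PREDICTS_EVENT, rs.Direction.HIGHER_PREDICTS_EVENT

sample = rs.simulate_dataset(rs.preset_model("ph_like"), n=2000, seed=11)
median = float(np.median(sample.values))
centered = rs.apply_transform(
    sample.values, rs.TransformSpec("center_square", median)
)

for method in ("hanley_mcneil", "delong", "bootstrap"):
    r = rs.compare_paired_aurocs(
        sample.values, centered, sample.labels,
        direction_a=L, direction_b=H, method=method, seed=42,
    )
    print(f"{method:14s} diff {r.diff:+.4f}  SE {r.se_diff:.4f}  "
          f"r {r.r:+.2f}  z {r.z:+.2f}  p {r.p:.2g}")
print()
print("All three agree that median-centering significantly improves the")
print("AUROC; the correlation r between the paired estimates is what keeps")
print("the difference SE smaller than the naive sum of the two SEs.")
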