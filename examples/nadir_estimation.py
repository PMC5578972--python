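"""Estimating the risk nadir and centering there.

When the nadir of a U-shaped risk relation is unknown, it can be estimated
as the minimum-event-rate quantile bin.  Folding the predictor at the nadir
(|x - c|) and squaring the distance ((x - c)^2) are monotone-related, so
they give identical AUROCs.
"""

import rocshape as rs

H = rs.Direction.HIGHER_PREDICTS_EVENT

sample = rs.simulate_dataset(rs.preset_model("ph_like"), n=20000, seed=5)

nadir = rs.estimate_nadir(sample, n_bins=20)
print(f"estimated risk nadir       : pH {nadir:.3f} (true model nadir 7.36)")

for kind in ("fold", "center_square"):
    spec = rs.TransformSpec(kind, center=nadir)
    transformed = sample.with_values(rs.apply_transform(sample.values, spec))
    a = rs.auroc_mann_whitney(transformed, H)
    print(f"AUROC after {kind:14s}: {a:.4f}")

raw = rs.auroc_mann_whitney(sample, rs.Direction.LOWER_PREDICTS_EVENT)
print(f"AUROC of raw pH (low=risk) : {raw:.4f}")
print()
print("fold and center_square agree exactly (|x-c| and (x-c)^2 rank")
print("subjects identically), and both beat the raw, uncentered predictor.")
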