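"""ROC shape diagnostics: how non-linear risk bends the curve.

Monotone risk gives the textbook concave curve; U-shaped risk a logit-like
inverse-sigmoidal curve; inverted-U risk a sigmoidal curve.  The latter two
cross the chance diagonal at an interior point where both cumulative
likelihood ratios equal one - the threshold there has no predictive value.
"""

import rocshape as rs

H = rs.Direction.HIGHER_PREDICTS_EVENT

cases = {
    "monotone risk": rs.preset_model("monotone_demo"),
    "U-shaped risk": rs.symmetric_u_model(),
    "inverted-U risk": rs.preset_model("inverted_u_500"),
}

for name, model in cases.items():
    sample = rs.simulate_dataset(model, n=5000, seed=3)
    curve = rs.empirical_roc(sample, H)
    shape = rs.classify_shape(curve)
    print(f"{name:16s} -> {shape.label:18s} "
          f"(above {shape.max_excursion_above:.2f}, "
          f"below {shape.max_excursion_below:.2f})")
    for f, t in shape.crossings:
        print(f"{'':16s}    crosses the diagonal at FPR = TPR = {f:.3f} "
              f"(LR+ = LR- = 1 there)")
print()
print("An interior diagonal crossing is the ROC fingerprint of a")
print("non-monotone risk relation; its location maps back to the risk")
print("nadir (or peak) on the predictor scale.")
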