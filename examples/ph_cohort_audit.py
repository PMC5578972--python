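"""Full audit of a pH-like cohort: raw vs mean- vs median-centered AUROC.

Emulates the structure of a critical-care cohort in which the worst
first-24-hour arterial pH has an asymmetric U-shaped relation to hospital
mortality (acidosis arm steeper).  Low pH predicts death, so the raw
predictor is analysed as lower-predicts-event; after squared-distance
centering, larger values mean larger risk.
"""

import rocshape as rs

config = rs.AnalysisConfig(
    preset="ph_like",
    n=5000,
    seed=7,
    direction=rs.Direction.LOWER_PREDICTS_EVENT,
    transforms=(
        rs.TransformRequest("center_square", "mean"),
        rs.TransformRequest("center_square", "median"),
    ),
)
report = rs.run_analysis(config)

print(f"n = {report['n']}  (events: {report['n_pos']})")
for entry in report["analyses"]:
    est = entry["estimate"]
    print(
        f"{entry['name']:22s} AUROC {est['auroc']:.3f} "
        f"(95% CI {est['ci_low']:.3f}-{est['ci_high']:.3f})  "
        f"shape: {entry['shape']['label']}"
    )
for comp in report["comparisons"]:
    r = comp["result"]
    print(
        f"{comp['b']:22s} vs raw: diff {r['diff']:+.3f} "
        f"(95% CI {r['ci_low']:+.3f} to {r['ci_high']:+.3f}), p = {r['p']:.2g}"
    )
print()
print("Median-centering beats mean-centering here because the cohort is")
print("left-skewed: the median sits closer to the risk nadir than the mean.")
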