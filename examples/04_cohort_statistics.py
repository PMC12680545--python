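"""Matched-cohort simulation and the group comparison of the BSI.

Generates a 10+10 matched fracture/control cohort calibrated to the
published group summaries (BSI effect -0.326), evaluates the Bone
Strength Index for every subject, and runs the normality-gated group
comparisons.
"""

from femrisk import (CohortSpec, compare_many, evaluate_cohort,
                     generate_cohort, metric_attribution, table_reconciled)

models = table_reconciled()
cohort = generate_cohort(CohortSpec(seed=0), model_set=models)
results = evaluate_cohort(cohort, models)

print("Per-subject results (first four):")
cols = ["id", "group", "stt_mm", "strength_kN", "max_force_kN",
        "argmax_metric", "bsi", "predicted_fracture"]
print(results[cols].head(4).to_string(index=False,
                                      float_format=lambda v: f"{v:.3f}"))

print("\nWhich metric produced the maximum impact force:")
print(metric_attribution(results).to_string(index=False,
                                            float_format=lambda v: f"{v:.0f}"))

print("\nGroup comparisons (fracture vs control):")
for comp in compare_many(results, ["bsi", "strength_kN", "max_force_kN",
                                   "stt_mm"]):
    print(f"  {comp.measure:>12}: fracture {comp.fracture.display():<22} "
          f"control {comp.control.display():<22} {comp.test} "
          f"p={comp.p_value:.4f}  d={comp.cohens_d:+.2f}")
print("\nA negative BSI difference with d near -1 reproduces the designed")
print("group effect; the permutation-level false-positive rate of the same")
print("test stays near the nominal 5% (see the acceptance suite).")
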